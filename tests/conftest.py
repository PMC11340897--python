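import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import vocabrank as vr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocabs() -> list[vr.Vocabulary]:
    return vr.builtin_vocabularies()


@pytest.fixture(scope="session")
def study_cfg() -> vr.SimulationConfig:
    """Study-condition config at reduced cohort size (exclusions active)."""
    return vr.default_config(seed=101, n_participants=120)


@pytest.fixture(scope="session")
def study_table(study_cfg) -> vr.RatingTable:
    return vr.simulate_study(study_cfg)


@pytest.fixture(scope="session")
def clean_table() -> vr.RatingTable:
    """A clean calibrated cohort: nobody fails any exclusion criterion."""
    cfg = vr.default_config(
        seed=7, n_participants=60, attention_fail_prob=0.0, overtime_prob=0.0
    )
    return vr.simulate_study(cfg)


def degenerate_config(seed: int = 0, n_participants: int = 10, **overrides):
    """Noise-free config whose phrase distributions are point masses at the
    published medians, so every implied ranking is the intended one."""
    conc = 1e8
    models = {
        key: vr.PhraseModel(
            phrase=key[2],
            alpha_shape=max(t[1], 0.5) / 100.0 * conc,
            beta_shape=max(100.0 - t[1], 0.5) / 100.0 * conc,
            target_q25=t[0],
            target_q50=t[1],
            target_q75=t[2],
        )
        for key, t in vr.QUARTILE_TARGETS.items()
    }
    defaults = dict(
        vocabularies=tuple(vr.builtin_vocabularies()),
        models=models,
        n_participants=n_participants,
        coherence_sd=0.0,
        noise_sd=0.0,
        lapse_prob=0.0,
        attention_fail_prob=0.0,
        overtime_prob=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return vr.SimulationConfig(**defaults)


def order_from_ranks(ranks: dict[str, float], vocabulary_id: str = "v") -> vr.WeakOrder:
    return vr.WeakOrder(participant_id="p", vocabulary_id=vocabulary_id, ranks=ranks)


def table_from_wide(wide: pd.DataFrame, vocabulary: vr.Vocabulary,
                    duration: float = 15.0, attention: bool = True) -> vr.RatingTable:
    """Build a RatingTable from a participants x phrases rating frame."""
    records = []
    for pid, row in wide.iterrows():
        for phrase, rating in row.items():
            if pd.isna(rating):
                continue
            records.append(
                {
                    "participant_id": str(pid),
                    "vocabulary_id": vocabulary.vocabulary_id,
                    "dimension": vocabulary.dimension_label,
                    "phrase": phrase,
                    "rating": float(rating),
                }
            )
    meta = pd.DataFrame(
        {
            "participant_id": [str(p) for p in wide.index],
            "duration_minutes": duration,
            "attention_pass": attention,
        }
    ).set_index("participant_id")
    rec = pd.DataFrame(
        records,
        columns=["participant_id", "vocabulary_id", "dimension", "phrase", "rating"],
    )
    return vr.RatingTable(rec, meta)
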