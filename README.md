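# vocabrank

Rank-agreement analysis for ordinal evaluative vocabularies.

Journals and assessment schemes increasingly grade research with short verbal
scales — e.g. a study's importance described as *landmark / fundamental /
important / valuable / useful*. Such a vocabulary only communicates if
readers recover its intended ordinal structure. `vocabrank` analyses
experiments that probe this: participants rate each phrase on a 0–100 slider,
and the package asks whether the ranking *implied* by each person's ratings
matches the ranking the vocabulary's designers *intended*.

It is written for survey methodologists and meta-researchers running (or
re-analysing) phrase-interpretation studies, and ships a calibrated
synthetic-rater generator so the entire pipeline runs, end to end, with no
external data.

## What it computes

For a vocabulary of n phrases with intended ranks 1..n and one participant's
ratings x₁..xₙ, the implied ranking is the midrank transform of the negated
ratings (ties share averaged ranks). From there:

- **Matched proportion** — the share of participants whose implied ranking is
  strict and equals the intended one, with a simultaneous 95% CI by the
  Sison–Glaz method for multinomial proportions (truncated-Poisson moments
  with an Edgeworth correction; all categories share the same half-widths).
- **Kendall's tau distance** K_d — the number of discordantly ordered phrase
  pairs between two rankings (equivalently, adjacent transpositions needed to
  convert one into the other), a pair tied in exactly one ranking counting ½.
  Reported normalised by its maximum n(n−1)/2 so vocabularies of different
  sizes are comparable.
- **Concordance matrix** — per phrase, the percentage of participants
  assigning it each observed rank; ties spread fractionally, so the matrix is
  doubly stochastic (rows and columns sum to 100%).
- **Paired vocabulary comparison** — within participants, a 2×2 table of
  matched/unmatched status under two vocabularies, tested with the exact
  (conditional binomial) McNemar test and its mid-p variant; the conditional
  odds ratio b/c gets a mid-p Clopper–Pearson CI mapped through
  OR = π/(1−π).
- **Response summaries** — per-phrase quartiles with percentile-bootstrap
  CIs, and Gaussian kernel densities on [0, 100] with boundary reflection.
- **Exclusion screen** — the sequential participant filter (attention check,
  overtime, incompleteness, too fast) with an auditable per-criterion log.

## Worked example

```python
>>> import vocabrank as vr
>>> voc = vr.builtin_vocabularies()[0]          # 5-phrase importance scale
>>> order = vr.implied_ranking(
...     {"landmark": 94, "fundamental": 83, "important": 72,
...      "valuable": 70, "useful": 60}, voc)
>>> vr.matches_intended(order, voc)
True
>>> ci = vr.sison_glaz_ci((59, 242))[0]         # 59 of 301 matched
>>> round(ci.point, 3), round(100 * ci.lower), round(100 * ci.upper)
(0.196, 15, 24)
```

The matched share is 19.6% with simultaneous 95% bounds of 15% and 24%: even
though this ranking *can* be recovered, four in five raters order at least
one phrase pair against the designers' intent.

The full synthetic study runs as a sequence of drivers:

```bash
python analysis/01_simulate_cohort.py --seed 0   # 461 raters, 21 phrases
python analysis/02_screen_participants.py        # exclusion cascade -> 301 retained
python analysis/03_response_distributions.py     # quartiles + densities
python analysis/04_ranking_agreement.py          # matching, K_d, concordance
python analysis/05_compare_vocabularies.py       # paired McNemar
```

With seed 0 the screen retains 301 of 461 simulated respondents and the
agreement step prints, per block, e.g.:

```
      elife / importance          matched  10.0% [7.0%, 13.3%]  (80 distinct rankings, mean normalised Kd 0.206)
alternative / importance          matched  60.5% [55.1%, 66.4%]  (10 distinct rankings, mean normalised Kd 0.045)
```

i.e. the five-phrase vocabulary with heavily overlapping middle phrases is
recovered by a small minority of raters, while the explicitly graded
alternative ("very high … very low importance") is recovered by a clear
majority — the qualitative fingerprint the analysis is designed to expose.
Each driver writes its tables under `results/`. The same pipeline is
available as a CLI (`vocabrank simulate | analyze | compare`) for arbitrary
rating CSVs and vocabulary JSON files.

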