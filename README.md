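# odorwords

Single-unit analysis of responses to odor-related words in human
mediotemporal regions — amygdala, hippocampus, entorhinal cortex,
parahippocampal cortex, and piriform cortex.

During a continuous word-recognition task, 300 visually presented object
words (100 shown once, 100 twice; 0.5 s display, 1.7–2.3 s jittered
inter-stimulus interval) are drawn from a pool of 200 words, half of them
odor-related and half control, matched on syllables, frequency,
concreteness, arousal, imageability and valence.  The analysis asks
whether single neurons and neuronal ensembles in olfaction-related
mediotemporal regions carry the odor aspect of a word's meaning.

The package implements the full statistical pipeline over spike-time and
trial-event tables, plus a seeded synthetic-session generator with known
ground truth that stands in for patient microwire recordings:

1. **Window firing rates and z-scores** — spike counts in four 500-ms
   post-stimulus bins over 0–2000 ms and a −200–0 ms baseline, on
   first-presentation trials; rate = count / duration; a unit is retained
   if its mean rate reaches 2 Hz in at least one window; z-scores
   standardize each unit's rates by the mean and SD of its baseline rates
   across trials: *z*(t, w) = (r(t, w) − μ_b) / σ_b.
2. **Per-unit screening** — stimulus-responsive units by four paired
   t-tests (each post window vs baseline), odor-associated units by four
   unpaired t-tests (odor vs control trials per window), flagged at
   Bonferroni-corrected *p* < 0.0125 (Benjamini–Hochberg optional).
3. **Prevalence tests** — per region, the number of flagged units is
   compared against chance with an exact one-sided binomial test,
   *p* = P(X ≥ k), X ~ Binomial(n, 0.05).
4. **Ensemble ANOVA** — split-plot mixed ANOVA of z-scored rates with
   within-unit factors CATEGORY (odor / living / food schemes) × TIME and
   between-unit factor REGION, Type III handling of unbalanced regions,
   LSD post-hocs and partial η² = F·df₁ / (F·df₁ + df₂).
5. **Cluster permutation tests** — per-bin t statistics on smoothed
   instantaneous rates, contiguous supra-threshold clusters scored by
   summed t, max-statistic permutation null (sign flips when paired,
   label shuffles otherwise).

## Worked example

The numbered drivers under `analysis/` run the stages in order:

```bash
python analysis/01_word_properties.py
python analysis/02_simulate_session.py --seed 1
python analysis/03_screen_units.py
python analysis/04_ensemble_anova.py
python analysis/05_cluster_permutation.py --seed 1
python analysis/06_calibration.py --seed 1
```

`01_word_properties.py` verifies stimulus matching:

```
    property       t  df         p  present
   syllables -0.9199 198    0.3588     True
   frequency  -1.255 198    0.2108     True
concreteness -0.8839 198    0.3778     True
     arousal  0.8305 198    0.4073     True
imageability -0.8305 198    0.4073     True
     valence   0.767 198     0.444     True
 odor_rating   21.95 198 6.307e-55     True
```

All six matched properties differ at *p* > 0.2 while the odor-relatedness
ratings separate the groups at *p* < 0.0001 — the stimulus contrast is
about odor meaning, not about general word properties.

`03_screen_units.py` analyzes the simulated session (195 units, 183
passing the 2 Hz filter with seed 1) and prints the two region tables,
e.g. for odor association:

```
Units with odor-related vs control differences

Number of units         Amygdala  Hippocampus  Entorhinal cortex  Parahippocampal cortex  Piriform cortex
Total                   54        53           19                 27                      30
Flagged                 9 (17%)   3 (6%)       3 (16%)            1 (4%)                  3 (10%)
Increase                5         2            1                  1                       2
Decrease                4         1            2                  0                       1
Binomial test: p-value  0.0013    0.50         0.067              0.75                    0.188

ground-truth check: 9 of 9 retained odor-associated units recovered (100%)
```

The amygdala row reads: 9 of its 54 retained units show a significant
odor/control difference; the chance of seeing 9 or more flagged units if
each unit had a 5% false-positive probability is *p* = 0.0013, so the
prevalence exceeds chance.  Every ground-truth odor-associated unit that
survived the rate filter was recovered.

The equivalent one-shot pipeline (library or CLI):

```bash
odorwords all --seed 1 --out-dir odorwords_output
```

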