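# tsl2screen

Analytics for target-based screening of small molecules against an RNA
stem-loop, and for the downstream splicing and structural readouts that
such a campaign produces.

The motivating system is the 19-nt terminal stem-loop (TSL2) spanning
the exon 7 / intron 7 junction of *SMN2*: its 3′ strand partially
sequesters the exon-7 donor site, and compounds that bind and open the
hairpin promote exon-7 inclusion — a therapeutic route for spinal
muscular atrophy. The package implements the full analysis chain of
such a campaign, with seeded synthetic-data generators standing in for
raw plates, gels, RNA-seq junction counts and structure ensembles, so
every stage is testable without external data:

1. **Fluorescence-displacement screening** (`screenstats`). Each
   compound is read against four control roles (A: dye+RNA+compound,
   B: dye+compound, C: dye+RNA, D: dye alone) and scored as

   activity (%) = 100 − ((A − B) / (C − D)) × 100,

   so 0 means no displacement of the RNA-bound dye and 100 means
   complete displacement. Assay quality is the screening-window
   coefficient Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|. Hits must exceed a 20%
   activity cutoff and then survive a two-tailed Welch test against
   DMSO controls with Bonferroni correction over the cutoff-passing
   family. Dose–response uses the four-parameter logistic
   y = bottom + (top − bottom)/(1 + (EC50/x)^h), fitted in
   log-concentration space by a `FourParamLogistic(conc, y).fit()`
   model/results pair.
2. **Exon-inclusion quantification** (`splicequant`). Percent inclusion
   from isoform band intensities 100·inc/(inc+skip); the normalised
   treatment effect %MIP = 100·(E7_treated − E7_DMSO)/(100 − E7_DMSO);
   qPCR fold changes by 2^−ΔΔCt; 2-aminopurine / native-PAGE / circular
   dichroism probe panels correlated against inclusion (Pearson, with
   sub-nm CD extrema by parabolic refinement).
3. **Junction-level differential splicing** (`psidiff`). Per-sample
   PSI = (I/2)/((I/2) + S) from summed inclusion-junction counts I and
   skipping counts S; events flagged at |ΔPSI| > 0.4 and > 0.65; a
   classifier separating SMN-recovery-mediated responses (significant
   in SMA cells, not in wild type) from off-targets (significant in
   both, same direction); exact hypergeometric enrichment of a donor
   motif (default AGGTAAG) among affected donor 9-mers.
4. **Hairpin ensemble geometry** (`hairpinstruct`). Multi-model PDB
   reading/writing, Kabsch superposition (proper rotations only),
   average pairwise bundle RMSD over heavy/stem/loop selections,
   per-residue RMSF about an iteratively refined mean, terminal-opening
   (C1′ 1–19) and loop-closure (8–12) distances, strict-threshold
   pentaloop/triloop classification, and free-vs-bound opening shifts
   with a moving-block bootstrap.
5. **Synthetic inputs** (`synthio`) and **orchestration**
   (`pipeline`, `cli`): every generator emits data plus a ground-truth
   table; one global seed fans out to per-stage sub-seeds, and
   identical config + seed reproduces byte-identical outputs.

## Worked example

```python
import numpy as np
from tsl2screen import synthio, screenstats

wells, truth = synthio.gen_plate(synthio.PlateConfig(seed=1))
acts = screenstats.plate_activities(wells)
is_ctrl = acts["compound_id"].str.startswith("DMSO")
ctrl = np.concatenate(acts.loc[is_ctrl, "activities"].to_list())
hits = screenstats.call_hits(acts[~is_ctrl], ctrl)
print("hits called:", int(hits["is_hit"].sum()), "of", len(hits))
print(hits.head(3)[["compound_id", "mean_activity", "p_adj", "is_hit"]]
      .to_string(index=False))

table, _ = synthio.gen_dose(synthio.DoseConfig(seed=1))
fit = screenstats.fit_4pl(table["concentration_uM"], table["response"])
print(fit.summary())
```

prints

```
hits called: 51 of 304
compound_id  mean_activity        p_adj  is_hit
    CMP0225      56.283263 8.348809e-09    True
    CMP0229      53.161379 2.146991e-03    True
    CMP0257      52.396781 9.354794e-11    True
4PL dose-response fit
------------------------------------------
n obs       32
converged   True
bottom             9.857  (se 2.55)
top                99.44  (se 2.55)
ec50               16.01  (se 1.6)
hill              0.9772  (se 0.104)
SSE                418.7
```

The plate carried 58 planted binders among 304 compounds (quadruplicate
wells, 5% multiplicative noise); 51 pass both the 20% cutoff and the
Bonferroni-corrected Welch test, with no false positives. The dose fit
recovers the planted EC50 of 16 µM from 8 doses × 4 replicates at 5%
noise, with standard errors from the Gauss–Newton covariance.

The same pipeline runs end to end from a YAML config:

```sh
tsl2screen run --config config.yaml     # simulate → screen → splicing → psi → struct
tsl2screen motif --affected a.fasta --background b.fasta --motif AGGTAAG
```

Each run writes per-stage TSVs (`hits.tsv`, `qc.tsv`, `ec50.tsv`,
`psi.tsv`, `rmsf.tsv`, `metrics.tsv`, `bundle_stats.tsv`, …), a
`summary.txt` and a `run_log.json` recording the fully resolved
configuration and seed.

## Layout

```
src/tsl2screen/
  synthio.py        seeded generators + ground truth
  screenstats.py    Eq.-1 activity, Z′, hit calling, 4PL model
  splicequant.py    % inclusion, %MIP, 2^-ddCt, probes, CD
  psidiff.py        PSI/dPSI, response classifier, motif enrichment
  hairpinstruct.py  Kabsch, bundle RMSD, RMSF, distances, loop states
  pipeline.py       YAML config validation, stage sequencing
  cli.py            `tsl2screen` console script
docs/methods.md     model and procedure notes, defaults, limitations
scripts/acceptance.py
tests/
```
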