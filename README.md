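# ramanbone

Non-destructive prescreening of archaeological bone for collagen survival
using FT-Raman spectroscopy.

Stable-isotope paleodiet work needs well-preserved bone protein, but the
usual indicators — % collagen yield, weight %C and %N, atomic C:N — are only
known *after* destructive demineralisation. In hot, seasonally wet burial
environments most excavated bone has lost nearly all of its protein, so a
cheap, non-destructive triage step saves both money and irreplaceable
skeletal material. `ramanbone` implements that triage: it integrates the
C-H stretch region (3060–2800 cm⁻¹, organic) and the symmetric phosphate
stretch ν₁ (983–930 cm⁻¹, mineral) of an FT-Raman bone spectrum, forms the
**organic-phosphate ratio**

```
R = A(C-H, 3060–2800) / A(PO₄³⁻ ν₁, 983–930)
```

aggregates triplicate scans, rejects fluorescence-swamped spectra, and
correlates R with the wet-chemistry yields to decide which bones are worth
destructive processing. A 41-sample archaeological reference cohort
(31 complete + 10 partial records) ships with the package, and a synthetic
spectrum/cohort generator provides ground-truth data for every stage.

The statistical toolkit covers Pearson r with Fisher-z intervals,
leverage / externally-studentized-residual influence diagnostics,
sensitivity re-analysis after removing influential points, Steiger's z
(and Williams' t) for comparing dependent overlapping correlations, atomic
C:N and δ-notation chemistry, and Youden-J threshold selection for the
screening decision.

## Worked example

```python
import ramanbone as rb

t1 = rb.load_table1()                  # 31 complete reference records
df = t1.complete_cases()
res = rb.pearson(df.raman_ratio, df.pct_collagen)
print(res.r, res.r_squared_pct, res.p_two_sided)
# 0.715478... 51.19093... 6.069e-06

sens = rb.sensitivity_reanalysis(
    df.raman_ratio, df.pct_collagen, ids=df.sample_id.tolist(),
    top_k_leverage=2, top_abs_residual=1,
)
print(sens.removed_ids, sens.result_after.r_squared_pct)
# ('33', '24', '41') 17.836876...

thr, ev = rb.choose_threshold(t1, collagen_threshold=1.0)
print(thr, ev.sensitivity, ev.specificity)
# 0.2085 1.0 0.6521739...
```

The ratio explains about half the variance in collagen yield (R² ≈ 51.2 %,
p < 0.001), but the association leans on a few well-preserved bones:
removing the two highest-ratio samples and one residual outlier drops R² to
17.8 % (p = 0.025). As a screen, a ratio cut of ≈ 0.21 catches every bone
with > 1 % collagen yield at 65 % specificity on this cohort — good triage,
not a quantitative collagen assay.

The same pipeline is scriptable from the shell:

```
ramanbone simulate --n 31 --seed 1 --outdir cohort/
ramanbone integrate --spectra cohort/spectra --out ratios.csv
ramanbone correlate --paired cohort/chemistry.csv --y pct_collagen \
    --sensitivity top2lev+top1resid --out report.json
ramanbone screen-eval --paired cohort/chemistry.csv --collagen-threshold 1.0
```

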