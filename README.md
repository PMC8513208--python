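# dndea

Dynamic network slacks-based Data Envelopment Analysis (DEA) for
benchmarking health systems — or any panel of decision-making units whose
internal structure is a small network of divisions linked within periods
and carrying stocks between periods.

## Who this is for

Health economists and operations researchers who want to score countries
(or hospitals, regions, ...) against an empirical best-practice frontier
when the system has *internal structure*: here, a **public health**
division (alcohol and tobacco exposure in, health-adjusted life expectancy
out) feeding a **medical care** division (CT density and health employment
in, discharges and consultations out) through preventive-service links
(immunisation, breast and cervical screening), with **bad carry-overs**
(infant mortality, cancer incidence) connecting consecutive periods.

## The model

For DMU *o*, divisions *k*, periods *t*, the input-oriented slacks-based
envelopment program chooses nonnegative intensities λ<sub>jk</sub><sup>t</sup>
and slacks subject to, per division and period,

```
x_ok = X_k λ_k + s⁻        (inputs)
y_ok = Y_k λ_k − s⁺        (outputs)
z_o  = Z λ + s             (links, sign and division per link mode)
z_o(t,t+1) = Z(t,t+1) λ_k^t + s_bad     (carry-overs, per class)
Z λ_k^t = Z λ_k^{t+1}      (carry-over continuity)
e λ_k^t = 1                (only under VRS)
```

and minimises the overall efficiency

```
θ*_o = Σ_t W^t Σ_k w^k [ 1 − (Σ_i s⁻_i/x_i + Σ_l s_l^in/z_l + Σ_c s_c^bad/z_c)
                             / (m_k + linkin_k + nbad_k) ]
```

with exogenous period weights W<sup>t</sup> and division weights
w<sup>k</sup> (uniform by default).  The same optimal slacks yield period
efficiency τ<sup>t</sup>, divisional efficiency δ<sub>k</sub>, and
period-divisional efficiency ρ<sub>k</sub><sup>t</sup>.  Scores lie in
(0, 1]; the program is linear and solved with HiGHS.

Around the engine the package provides:

* **Malmquist productivity** per division between two periods, decomposed
  as MI = CU × FS (catch-up × frontier shift) from mixed-period
  slacks-based distances, with geometric-mean aggregation across divisions;
* **Tukey box-plot outlier screening** (per variable and period, fences
  Q1 − k·IQR / Q3 + k·IQR) with before/after score comparison;
* a **kernel density-equality test** (integrated squared difference of
  KDEs, pooled-bootstrap p-value) for comparing CRS and VRS score
  distributions;
* a **synthetic panel generator** with planted frontier membership and
  known inefficiency depth, for end-to-end validation;
* the embedded **seven-country OECD panel** (AUT, FIN, GRC, CHL, JPN, MEX,
  TUR observed in 2000/2008/2016) and the re-keyed published 36-country
  score tables.

## Worked example

```python
from dndea import builtin_oecd7_fixture, evaluate_all, ModelOptions

panel = builtin_oecd7_fixture()
scores, failures = evaluate_all(panel, ModelOptions(returns_to_scale="CRS"))
for dmu, s in scores.items():
    print(f"{dmu}: overall={s.overall:.4f}  periods=" +
          " ".join(f"{t}:{v:.4f}" for t, v in s.period.items()))
```

prints

```
AUT: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
FIN: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
GRC: overall=0.9864  periods=2000:0.9593 2008:1.0000 2016:1.0000
CHL: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
JPN: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
MEX: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
TUR: overall=1.0000  periods=2000:1.0000 2008:1.0000 2016:1.0000
```

Six of the seven countries are mutually efficient in every period — they
span the frontier of this sub-panel, consistent with their published
scores of 1 against the full 36-country frontier.  Greece is slightly
inside the frontier in 2000 (period score 0.9593, never below its
published 36-country score of 0.9188, since shrinking the reference set
can only raise a DEA score) and efficient thereafter.

The same analysis runs from the shell:

```sh
dndea run --fixture --seed 1 --out-dir out/      # full pipeline
dndea evaluate --fixture                          # score table only
dndea synth --n-dmus 20 --seed 1 --out panel.csv  # synthetic panel
```

`dndea run` writes `scores.csv`, `slacks.csv`, `summary.json`,
`outliers.csv`, `comparison.csv`, `malmquist.csv`, `profiles.csv`,
`densitytest.json` and a `run.log` recording every modelling default.

## Layout

```
src/dndea/panel.py         panel container, validation, CSV I/O, OECD fixture
src/dndea/engine.py        envelopment LP and the four score families
src/dndea/productivity.py  Malmquist index, decomposition, profiles
src/dndea/outliers.py      Tukey screen and before/after comparison
src/dndea/density.py       kernel density-equality test
src/dndea/synthetic.py     generator with planted ground truth
src/dndea/reference.py     re-keyed published 36-country tables
src/dndea/report.py        pipeline and summary statistics
src/dndea/cli.py           command-line interface
docs/methods.md            modelling choices and their rationale
```
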