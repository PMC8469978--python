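# opbias

Quantitative pharmacology of GPCR agonist bias: radioligand-binding fits,
operational-model-of-agonism fitting, relative intrinsic activities and
ΔΔlog(τ/K_A) bias factors, built around the muscarinic acetylcholine
receptor (M1–M5) / Gα16-fusion experimental design.

## The problem

Covalent receptor–Gα16 fusion proteins force 1:1 receptor–G-protein
stoichiometry and exclude endogenous G proteins, so the inositol-phosphate
(IPx) response of each fusion reports signalling through Gα16 alone.
Comparing how strongly different agonists drive that one pathway across
receptor subtypes — relative to a reference agonist (carbachol) — reveals
agonist bias between receptors. `opbias` implements the complete analysis
chain for this design, for pharmacologists who have (or want to simulate)
plate-level binding and concentration–response data:

* **saturation binding** — specific binding `y = B_MAX·x/(K_D + x)` on
  depletion-corrected free radioligand, giving pK_D and B_MAX (pmol/mg);
* **competition binding** — one- vs two-site displacement selected by an
  extra-sum-of-squares F-test (α = 0.05), with Cheng–Prusoff conversion
  `K_I = IC50 / (1 + [D]/K_D)`;
* **functional response** — Hill fits
  `y = 1 + (E′_MAX − 1)·xⁿ/(EC50ⁿ + xⁿ)` with bottom fixed at basal (= 1),
  plus a flat-vs-Hill F-test that detects non-coupled constructs;
* **operational model of agonism** (Black–Leff) — the two-step procedure:
  a shared system ceiling E_MAX per (receptor, pathway) characterised
  globally over internal-standard agonists, then per-experiment
  `y = 1 + (E_MAX − 1)·τ·x/(K_A + (τ+1)·x)` fits with E_MAX fixed, giving
  operational efficacy τ and agonist dissociation constant K_A
  (`pEC50 = pK_A + log10(1+τ)`);
* **bias quantification** — relative intrinsic activity
  `RA_i = (E′_MAX,a/EC50,a)/(E′_MAX,ref/EC50,ref) = (τ_a/K_A,a)/(τ_ref/K_A,ref)`,
  transduction coefficients log(τ/K_A), between-receptor bias factors
  `10^ΔΔlog(τ/K_A)`, significance flags (ANOVA + Tukey HSD) and ranked
  orderings with tie groups;
* **synthetic experiments** — a fully seeded generator reproducing the
  study designs (6-point 63–2000 pM saturation in quadruplicate, 1 nM
  radioligand competition, triplicate 9-point IPx curves over a basal of
  2–3% incorporated radioactivity, biphasic wild-type vs flat fused cAMP).

## Worked example

Closed-form operational identities from a published fusion-receptor row
(carbachol at M2–Gα16: apparent maximum E′_MAX = 18, system E_MAX = 30.7;
oxotremorine at M2–Gα16: pEC50 = 8.22, τ = 2.8):

```python
>>> from opbias.models import HillFit, hill_to_operational, pka_from_pec50
>>> hill_to_operational(HillFit(pEC50=6.99, EmaxPrime=18.0, nH=1.0),
...                     30.7, baseline="plain").tau
1.4173228346456694
>>> pka_from_pec50(8.22, 2.8)
7.6402164033831905
```

τ ≈ 1.42 is carbachol's operational efficacy (it occupies about 59% of
receptors at half-maximal system response), and pK_A ≈ 7.64 is
oxotremorine's operational affinity, lower than its potency because
receptor reserve shifts EC50 left of K_A by log10(1+τ).

A full virtual study from the shell — simulate, fit, and rank receptor
preference per agonist:

```bash
opbias simulate --seed 1 --out out/
opbias fit-functional --in out/data_long.csv --out out/functional.csv
opbias bias --from-params out/functional.csv --out out/bias.csv
```

Table mode recomputes bias straight from a published parameter table
(no raw curves). On the packaged Gα16-panel parameters it prints, among
others:

```
arecoline: M2 > M4 ~ M3 > M5 > M1
xanomeline: M2 > M5 > M4 > M1 > M3
```

i.e. arecoline prefers M2 over every other subtype, M4 and M3 are
statistically tied, and M1 is weakest — orderings decided by pooled
two-sample t-tests on the across-experiment RA_i summaries.

The polar-plot report (`--plot`) shows each agonist's RA_i across
receptors as fold over its lowest-activity receptor.

## Module map

| module | contents |
| --- | --- |
| `opbias.models` | domain types and all forward-model equations |
| `opbias.binding` | saturation and competition fitting |
| `opbias.functional` | Hill fits, flat test, two-step operational fit |
| `opbias.bias` | RA_i, bias factors, rankings, ANOVA/Tukey |
| `opbias.simulate` | seeded virtual-experiment generator |
| `opbias.datasets` | packaged published parameter tables |
| `opbias.io`, `opbias.cli`, `opbias.pipeline` | long-CSV formats, CLI, orchestration |

See `docs/methods.md` for the model conventions, identifiability analysis
and numerical choices.
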