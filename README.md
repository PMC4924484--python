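# crykinetics

Kinetic modeling of the *Arabidopsis* cryptochrome flavin photocycle:
from absorbance spectra (or whole-seedling biological readouts) to rate
constants, photoconversion cross sections and quantum yields.

## The problem

Plant cryptochromes (cry1 and cry2) are blue-light photoreceptors whose FAD
chromophore cycles between three redox states:

```
FADox --k1--> FADH°  --k2--> FADH⁻
FADox <--k1b-- FADH°
FADox <---------k2b--------- FADH⁻
```

Blue light drives FADox → FADH° (rate k₁) and blue/green light drives
FADH° → FADH⁻ (rate k₂); both reduced states reoxidize in the dark at
light-independent, oxygen-dependent rates (k₁b, k₂b).  The neutral radical
FADH° is the signaling ("lit") state, so the biological question — how much
receptor is active at a given light intensity? — reduces to a kinetics
question: what are the four rates, and what fraction of an absorbed photon
actually drives each redox transition?

With concentrations normalized to total flavin, the dynamics are a linear
first-order system (d[FADox]/dt = −k₁[FADox] + k₁b[FADH°] + k₂b[FADH⁻], and
so on).  Two spectral bands suffice to observe it: normalizing absorbance to
the dark spectrum and using ε_H(450) = ε_H(560) = ε_ox(450)/2,

    [FADox](t) = A(450,t) − A(560,t)        [FADH°](t) = 2·A(560,t)

(FADH⁻ does not absorb in 400–570 nm and follows by conservation).  The
light-driven rates are proportional to photon fluence rate, k = σ·I, and
the photoconversion cross section σ links to the quantum yield φ through
σ = 2.3·ε·φ.  A dose–response series of end-of-illumination concentrations
therefore yields σ (through-origin fit of k vs. I) and hence φ.  The same
machinery applies in vivo by treating a biological readout (hypocotyl
length for cry1, cry2 protein level for cry2) as an affine, order-reversing
proxy for [FADH°].

## What the package provides

- `kinetics` — the three-state ODE (fixed-step RK4 integrator), two-state
  closed forms, dark-reoxidation decay, half-lives, steady states.
- `spectra` — Beer–Lambert conversions between band absorbances and
  redox-state concentrations, dark normalization, extinction-coefficient
  units (M⁻¹cm⁻¹ ↔ mol⁻¹m²).
- `estimation` — Levenberg–Marquardt reoxidation fits (k₁b, τ½), bracketed
  root-finding inversions for k₁ (two-state) and k₂ (three-state),
  through-origin cross-section fits, quantum yields, condition summaries.
- `invivo` — readout → [FADH°] mapping and the in vivo σ/φ pipelines
  (steady-state or timed-exposure modes).
- `synthetic` — generators for every input kind (recovery spectra, blue and
  green dose series, in vivo readouts) with known ground truth, controlled
  noise and deterministic seeding.
- `io` / `pipeline` / `cli` — CSV + YAML round-tripping, end-to-end analysis
  stages, and a `crykinetics` command-line tool.

## Worked example

Simulate a blue-light dose–response experiment (cry2-like: σ₁ = 1.6×10⁻⁴
µmol⁻¹m², k₁b = 0.003 s⁻¹, 20-s illuminations at 25–400 µmol m⁻²s⁻¹,
noiseless) and analyze it back:

```sh
$ crykinetics simulate --kind blue-dose --out data --seed 1
wrote synthetic blue-dose dataset to data

$ crykinetics fit-blue --input data/spectra.csv --out fit \
      --receptor cry2 --k1b 0.003 --t-illum 20
sigma1 = 0.00016 umol^-1 m^2 (FADH. fit), phi1 = 0.136563; mean phi1 = 0.136563
```

The fit recovers the generating cross section exactly (0.00016 µmol⁻¹m² =
160 mol⁻¹m²) and converts it with the cry2 extinction coefficient
(509.4 mol⁻¹m²) to a quantum yield φ₁ = 0.137: roughly one photon in seven
absorbed by oxidized cry2 flavin produces the signaling radical.  The same
flow works for dark-recovery data:

```sh
$ crykinetics simulate --kind reoxidation --out reox --seed 1
$ crykinetics fit-reoxidation --input reox/spectra.csv --out reoxfit \
      --condition "cry2 pH 7.5"
k1b (FADH. fit) = 0.003 1/s, mean half-life = 231 s
```

i.e. once the light is off, the radical pool halves every ~231 s.  Each
command also writes a machine-readable report (`fit.json`, `fit.csv`) with
full-precision values, display-rounded companions, and per-fit diagnostics
(R², point counts, which species was fitted); `crykinetics report` merges
such rows into one condition-by-condition summary table.

The same analysis in Python:

```python
from crykinetics import SyntheticConfig, analyze_blue_dose, Species
from crykinetics.synthetic import generate_blue_dose_series

config = SyntheticConfig()                    # cry2 pH 7.5 defaults
records, design, truth = generate_blue_dose_series(config)
result = analyze_blue_dose(records, k1b=0.003, eps_ox_450=509.4)
print(result[Species.FADH_RAD].phi)           # 0.13656304945289546
```

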