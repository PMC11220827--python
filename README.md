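# ngra — exposure-led next-generation risk assessment for read-across

`ngra` is a toolkit for conducting an exposure-led, non-animal ("NGRA")
safety assessment of a cosmetic ingredient by read-across from a data-rich
analogue. It implements the complete tiered workflow for the isoflavone pair
daidzein (target) / genistein (source) — deriving the highest concentration
of the target that can safely be used in a leave-on body lotion — and every
stage is reusable for other chemical pairs: the packaged fixtures are just
one configuration of the pipeline.

It is written for risk assessors and toxicokinetic modellers who need the
individual computations (PBPK dosimetry, point-of-departure derivation,
bioactivity-exposure ratios) as tested, composable library functions rather
than spreadsheet arithmetic.

## What it computes

**PBPK dosimetry.** A perfusion-limited whole-body compartmental model
(gut, liver, kidney, skin, rest-of-body, plasma) with first-order oral and
dermal absorption, skin first-pass metabolism competing with dermal uptake,
and hepatic clearance of the unbound fraction. For tissue *i* with volume
*V<sub>i</sub>*, blood flow *Q<sub>i</sub>* and tissue:plasma partition
*K<sub>p,i</sub>*:

    dA_i/dt = Q_i (C_p − C_i / K_p,i)         (+ CL_h fu C_liv/K_p,liv in liver)

Repeated dosing runs to steady state (day 7 of once-daily application);
C<sub>max,total</sub> is read from the final dosing interval and
C<sub>max,fu</sub> = fu × C<sub>max,total</sub>. Monte-Carlo lognormal
parameter variability yields population mean and CI5–95% metrics, and
bisection inverts the model (reverse dosimetry: target plasma concentration
→ external dose).

**Point of departure.** Gene-level benchmark doses aggregate into pathway
medians (3- or 5-gene filters); the governing PoD comes from *functional*
assay classes (receptor transactivation first — receptor binding flags
targets but never sets the PoD); ±S9 assay pairs collapse to their minimum;
then NOEC = LOEC/3 and the safe internal concentration = NOEC/3.3
(intra-individual variability).

**Exposure and margins.** SCCS-convention applied dose
(g/day × mass fraction / cm²), systemic exposure dose, the
bioactivity-exposure ratio BER = PoD<sub>internal</sub> / exposure (BER > 1
⇒ acceptable margin) and the traditional margin of safety.

**Evidence and orchestration.** A read-across dossier (physicochemical
similarity verdicts, profiler concordance, potency ratios) gates the
10-step tiered workflow, which emits a JSON + Markdown report with a
decision log and uncertainty ledger. Seeded synthetic generators produce
every input the pipeline consumes, for testing and simulation studies.

## Worked example

```python
from ngra import datasets
from ngra.pod import AssayPanel, select_pod, derive_pod
from ngra.pbpk import DosingSchedule, reverse_dosimetry
from ngra.exposure import compute_ber

panel = AssayPanel.from_dataframe(datasets.assay_panel_table(), "daidzein")
pod = derive_pod(select_pod(panel))
print("selected:", pod.selected_assay.assay_id, pod.selected_assay.s9, pod.loec, "nM")
print("display:", pod.display())

params = datasets.load_pbpk_config("daidzein-human-dermal")
sched = DosingSchedule(route="dermal", dose=1.0, area_cm2=15670.0, n_doses=7)
print(f"safe external dose: {reverse_dosimetry(params, sched, 10.0):.2f} ug/cm2")
ber = compute_ber(10.0, 5.95)
print("BER:", ber.display, ber.interpretation)
```

prints

```
selected: calux_er_alpha plus 100.0 nM
display: {'loec_nM': 100.0, 'noec_nM': 33.0, 'safe_internal_concentration_nM': 10.0}
safe external dose: 0.50 ug/cm2
BER: 1.7 acceptable_margin
```

Reading: the estrogen-receptor-α transactivation LOEC of 100 nM (the +S9
variant, by the minimum rule) governs the PoD; dividing by 3 and 3.3 gives
a safe internal concentration of 10 nM; inverting the calibrated human
dermal model converts that to 0.5 µg/cm² — a 0.1% body lotion — and the
BER against the mean total plasma C<sub>max</sub> at that use level is 1.7,
an acceptable margin.

The same assessment runs end to end from the shell:

```bash
ngra run-ngra --out-json report.json --out-md report.md
ngra simulate --config genistein-rat-oral --route oral --dose 0.3
ngra reverse-dose --config daidzein-human-dermal --target-nm 10
ngra synth --seed 1 --outdir synthetic_out
```

## Layout

- `src/ngra/pbpk.py` — PBPK engine (forward, population, reverse, skin first-pass)
- `src/ngra/pod.py` — assay panels, pathway BMD aggregation, PoD selection and safety factors
- `src/ngra/exposure.py` — scenarios, BER, MoS
- `src/ngra/readacross.py` — analogue-suitability dossier
- `src/ngra/biokinetics.py` — in vitro exposure metrics (AUC, nominal adequacy, intracellular)
- `src/ngra/synthetic.py` — seeded generators for all pipeline inputs
- `src/ngra/datasets.py` — packaged, checksummed case-study fixtures and calibrated PBPK configs
- `src/ngra/workflow.py`, `src/ngra/cli.py` — 10-step orchestration and CLI
- `docs/methods.md` — model documentation, assumptions and limitations
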