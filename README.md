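# starkit

Kinetic modelling, circuit composition and plate-reader analysis for
cleavable regulatory-RNA arrays — single transcripts carrying tandem copies
of a small transcription-activating RNA separated by cleavable insulators,
so that one transcription event releases a tunable number of activator
molecules.

## What's inside

| module | contents |
| --- | --- |
| `starkit.model` | ODE model of one array transcription unit (array transcript → cleavage-released activator pool → saturating activation of an output RNA with leak), closed-form steady state, time courses, input–output curves, copy-number gain tables |
| `starkit.circuits` | composition into circuits: inducible amplifier, three-unit activation–activation cascade with an array amplifier between nodes, 1-to-2 multiplex motif with copy-number weights; topological closed-form evaluation cross-checked against joint ODE integration |
| `starkit.plate` | measurement pipeline: media-blank correction → FL/OD → autofluorescence subtraction, fold activation, standard curves (inducer → relative promoter activity), copy-number Pearson correlation (df = N − 2), Welch t-test, one/two-way ANOVA + Tukey HSD |
| `starkit.synth` | synthetic plate-reader datasets with model-derived means, lognormal biological noise, additive read noise, blank/control wells and inducer dose series; least-squares parameter recovery with identifiability checks |
| `starkit.assembly` | Golden-Gate-style in-silico array assembly with 4-nt fusion overhang validation, IUPAC-aware forbidden-site scanning on both strands, and direct-repeat (instability-risk) reporting |

## CLI

```sh
starkit simulate --n 4 --u 0.5 --t-end 100 --out traj.csv
starkit sweep --vary u --grid 0:1:0.05 --copies 1,2,4,6,8 --out curve.csv
starkit gain --copies 1,2,4,6,8 --u 0.5
starkit cascade --array-copies 4 --plasmids 10,5,1 --out cascade.csv
starkit multiplex --n 2 --m 1 --out mp.csv
starkit synth --seed 7 --out plate.csv            # synthetic copy-sweep plate
starkit analyze --plate plate.csv --out report/   # corrected.csv + report.json
starkit design --copies 4 --out array.fa          # assembled array + JSON report
```

Model parameters can be supplied as JSON/YAML files keyed by the
`ModelParams` field names (`u, k_c, d_A, d_S, d_G, eps, n, a_T, K, lam`);
plates are tidy CSV
(`well, role, construct, copies, inducer, replicate, OD600, FL_GFP, FL_RFP`).

## Notes

* Default kinetic constants are documented estimates in arbitrary units,
  not fitted values; all qualitative behaviours (linear copy-number gain in
  the sub-saturating regime, output saturation in input, additive leak
  shift) are asserted by the test suite.
* Default part sequences in `starkit.assembly` are placeholders with valid
  overhang chemistry; swap in real parts via FASTA
  (`>id category=STAR uo=AATG do=GCTT`).
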