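# apjbias

Structural and pharmacological diagnostics of **biased agonism** at the
apelin receptor (APLNR/APJ), a class-A GPCR that signals through both Gi
proteins and β-arrestin. The package is aimed at computational
pharmacologists who want to ask, from an MD trajectory of an active-state
receptor and from recruitment-assay dose–response tables, whether a ligand
steers the receptor toward the β-arrestin or the G-protein pathway.

## What it computes

**Structural side.** Two conformational markers are combined:

1. *TM5–TM7 tyrosine hydrogen bond.* A persistent hydrogen bond between
   Tyr221 (TM5) and Tyr309 (TM7) closes the intracellular cavity and marks
   a β-arrestin-competent conformation. The package measures the
   acceptor-O→donor-H distance in both donor directions, reports their
   means, and evaluates the fraction of frames whose donor–acceptor O···O
   distance lies in the optimal hydrogen-bond band (2.7–3.3 Å).
2. *G-protein docking clash.* A representative conformer (the top GROMOS
   cluster centroid at a 0.2 nm Cα-RMSD cutoff) is superposed onto a
   receptor/G-protein template complex; the template receptor is
   discarded and the van-der-Waals overlap between the receptor's Arg127
   (TM3) and the Gα Tyr356 is evaluated
   (clash ⇔ d < r₁ + r₂ − 0.4 Å on any heavy-atom pair).

Persistent bond + clash → `beta-arrestin-biased`; neither →
`G-protein-competent`; anything else → `indeterminate`.

Supporting observables: Kabsch superposition and RMSD traces, pair
distances, geometric hydrogen-bond detection (d ≤ 3.5 Å, ∠H–D–A ≤ 30°),
Shrake–Rupley SASA with Monte-Carlo occupied volume, ligand-contact
residues, and GROMOS (Daura) neighbour-counting clustering.

**Pharmacological side.** Dose–response tables (concentration in M,
response in RLU) are fitted with

* saturation binding, `B(x) = Bmax·xʰ / (Kdʰ + xʰ)`;
* the Black–Leff operational model of partial agonism,
  `E(A) = Em·τⁿAⁿ / ((K_A + A)ⁿ + τⁿAⁿ)`, where τ is efficacy (the inverse
  of the receptor fraction needed for half-maximal response) and K_A the
  functional affinity;
* Hill inhibition, `R(x) = bottom + (top − bottom)/(1 + (x/IC50)ˢ)`;

plus Bmax normalisation against a reference agonist (percent of the
natural agonist's maximum). Fits use log-parameterised deterministic
multi-start least squares — same data, same answer, no seeds.

A synthetic-data module generates toy receptors, trajectories whose
tyrosine-pair distance follows a mean-reverting process with an optional
regime switch (emulating a conformational transition part-way through a
run), template complexes at controlled steric separations, and noisy assay
tables — so the whole pipeline is testable with known ground truth.

## Worked example

```python
import apjbias as ab

receptor = ab.make_toy_receptor(pair_distance_A=3.0)
traj = ab.make_trajectory(
    ab.TrajectorySpec(n_frames=10_000, pair_mean_A=3.0,
                      transition_frame=7_000, post_mean_A=6.0, seed=1),
    receptor,
)
template = ab.make_template_complex(separation_A=1.0)
report, tyr = ab.run_bias_pipeline(traj, template)
print(report.to_text())
```

prints

```
bias call: beta-arrestin-biased

clustered 200 frames (stride 50) at 0.2 nm -> 1 cluster(s); centroid frame 0
tyrosine-pair window occupancy 0.699 (threshold 0.5) -> hydrogen bond persistent
receptor/G-protein residue pair minimum distance 1.02 A; 1 van-der-Waals overlap(s) (tolerance 0.4 A) -> clash (computed from vdW overlap, not visual inspection)
call: beta-arrestin-biased
```

Read it as: the tyrosine pair stayed inside the hydrogen-bond band for
69.9% of frames (the generator switched the target distance from 3.0 Å to
6.0 Å at 70% of the run), which exceeds the 0.5 persistence threshold, and
after superposition onto the template the Arg127/Tyr356 pair overlaps
sterically — so the G protein cannot dock and the run is called
β-arrestin-biased. A run held at 6.1 Å with a template separation of 8 Å
comes out `G-protein-competent`.

The same stages are available from the shell:

```sh
apjbias simulate --kind trajectory --n-frames 10000 \
    --transition-frame 7000 --post-mean 6.0 --out-dir run/
apjbias simulate --kind template --separation 1.0 --out-dir run/
apjbias bias-report --traj run/trajectory.pdb --template run/template.pdb \
    --out-dir run/report/
apjbias fit --data assay.csv --model hill_binding \
    --reference apelin-13 --out fits.json
```

Every command writes a `.runlog.yaml` next to its outputs recording the
package version and the echoed configuration.

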