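# putachannel

Trajectory and structure analysis of substrate channeling in **PutA**
(proline utilization A), the bifunctional bacterial enzyme that oxidises
L-proline to L-glutamate in two steps.  Its proline dehydrogenase (PRODH)
and L-glutamate-γ-semialdehyde dehydrogenase (GSALDH) active sites sit
~42 Å apart, connected by a buried tunnel through which the reactive
intermediate Δ¹-pyrroline-5-carboxylate (P5C) is channeled without release
to bulk solvent.  The package is aimed at structural biologists and
simulators who want to quantify that channeling behaviour from replicate
MD ensembles and from deposited coordinate models.

## What it computes

For replicate trajectories of the product complex (reduced PRODH site with
P5C bound):

- **Ligand tracking** — per-frame displacement
  d(t) = RMSD of the ligand heavy atoms from their frame-0 pose (no
  internal refit), zone classification into active site (d < 10 Å), tunnel
  (10 ≤ d < 30 Å) and distal region, debounced **release** detection
  (d ≥ 10 Å sustained), **dissociation** detection (loss of all protein
  contact sustained), and pooled displacement histograms.
- **Ion-pair gate analysis** — the Arg488 Cζ – Glu225 Cδ distance series,
  classified into closed [0, 5), semiopen [5, 8) and open [8, ∞) Å states;
  distance distributions conditioned on replicate outcome; and the
  necessity/sufficiency report: the fraction of release events with a
  non-closed gate, and the fraction of replicates with long-lived open
  episodes (≥ 10 Å for ≥ 500 ns) but no release.
- **Docking-site persistence** — maximal runs of the Arg312 NZ – P5C
  carboxylate-carbon contact (< 5 Å).
- **Tunnel hydration** — water-oxygen census inside an explicit tunnel
  region (union of spheres along an arc-length-parameterized centerline).
- **Backbone RMSF** — per-residue, referenced to the time-averaged
  structure, averaged over replicates.

For deposited coordinate models (PDB/mmCIF, occupancy- and altloc-aware):
bond distances, χ1 rotamers, the Bürgi–Dunitz approach angle Nu–C–O, the
flavin isoalloxazine **butterfly bend** (angle between least-squares planes
of the two outer rings), the static gate distance, ligand occupancies and
the inter-active-site separation.

A **synthetic trajectory generator** reproduces the statistical structure
of the study ensemble (21 replicates × 2 μs at 1 ns sampling): a two-state
Markov / Ornstein–Uhlenbeck gate, a ligand diffusing on a tunnel
free-energy profile with a docking well at 17.5 Å whose inner barrier
crossing is only permitted while the gate is not closed, ~280 tunnel
waters, and a fluctuating protein scaffold — together with ground-truth
event labels, so every detector is testable for exact recovery.

## Worked example

```bash
putachannel simulate --replicates 21 --frames 2000 --seed 2026 --out out/
```

or equivalently, run the numbered drivers under `analysis/`
(`python analysis/01_simulate.py`, ... `06_geometry.py`), which wrote the
tables under `results/`.  With seed 2026 they print:

```
outcomes: {'remained': 5, 'channeled': 14, 'dissociated': 2}
detected outcomes {...}; exact recovery of ground truth: True
in-tunnel histogram mode at 17.25 A (docking well at 17.5 A)
necessity fraction (gate not closed at release): 1.0
replicates with gate closing after release: 11
tunnel waters: mean 280.0, band [247, 313] (1st/99th pct)
tunnel helices mean RMSF 0.52 A (max 0.52); lid mean 2.08 A
```

Reading: most replicates release P5C into the tunnel within 2 μs while a
minority keep it in the PRODH site; the event detectors reproduce the
generator's ground-truth labels frame-exactly; the ligand accumulates at
the docking well; the gate is never closed at the moment of release
(necessity = 1.0) although it often closes again afterwards; the tunnel
holds ~280 waters on average; and the tunnel-lining helices are the
stiffest part of the scaffold (RMSF ≪ 1 Å).

For deposited models, the same geometry report the drivers demonstrate on
constructed fixtures runs directly on a coordinate file:

```bash
putachannel geometry 9C34.cif --chain A --out geo/
```

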