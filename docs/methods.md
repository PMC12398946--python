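# Methods

## The system being modelled

PutA couples two active sites through a buried tunnel.  After the PRODH
flavin oxidises proline, the product P5C must travel ~30–40 Å along a
channeling coordinate to the GSALDH site; an Arg488–Glu225 salt bridge
("the gate") controls the exit from the PRODH site into the tunnel.  The
analyses in this package quantify that process from replicate
trajectories: when and whether the ligand leaves the active site, what the
gate was doing at that moment, where the ligand pauses en route, how
hydrated the tunnel is, and how stiff the tunnel walls are.  A companion
set of structure metrics measures the catalytic-cycle geometry (flavin
butterfly bend, covalent bond lengths, rotamers, nucleophilic approach
angle) in deposited coordinate models.

## Synthetic ensemble: model and assumptions

Real replicate MD of this system (tens of microseconds of explicit-solvent
simulation) is far beyond desk scale, so the package ships a generator
that reproduces the *statistical structure* of such an ensemble and, with
it, exact ground-truth event labels.  The default configuration — the
study conditions — is 21 replicates × 2000 frames at 1 ns per frame.

**Gate.**  A latent two-state Markov chain (closed/open) with per-ns rates
`k_open = k_close = 0.001` switches the mean of an Ornstein–Uhlenbeck
distance process (means 4 Å and 12 Å, stationary SD 0.7 Å, relaxation
10 ns, started closed as in the crystal structures).  These rates give a
~0.5 stationary open fraction and open episodes of ~1 μs, so individual
replicates show the long-lived, rarely switching gate behaviour the
analysis must cope with.

**Ligand.**  Overdamped diffusion (D = 1 Å²/ns, Euler step 1 ns) on a 1-D
free-energy profile along the tunnel coordinate s: Gaussian wells at the
active site (s = 0, 3.0 kT, σ 3 Å) and the docking site (s = 17.5 Å,
3.0 kT, σ 3 Å), a small inner barrier at s = 10 Å (1.0 kT), an exit
barrier at s = 30 Å (3.0 kT) and a gentle outward tilt beyond 32 Å; walls
at s = 0 and 45 Å reflect.  The 3-D position is the (straight) centerline
point at s plus isotropic lateral noise (SD 0.3 Å); the ligand's heavy
atoms ride rigidly on that centroid (its internal mobility is not
modelled).  Well depths and barriers were fixed once so that, at the
default conditions, roughly two thirds of replicates channel and complete
dissociation is rare (of order one replicate per ensemble) — the outcome
mix itself is emergent, never assigned.

**Gate–ligand coupling.**  A proposed move is rejected outright if it
would carry the ligand's displacement from its start pose across the inner
barrier from below while the concurrent gate distance is below 5 Å
(i.e. while the gate is in its closed state as the analysis defines it).
Opening therefore *permits* escape but never causes it.  Judging
"closed" from the emitted distance (not the latent Markov state) makes
the guarantee exact in the observables the analysis sees: at any release
frame the gate distance is ≥ 5 Å, so the necessity fraction is exactly
1.0 at every seed.  Judging it from the latent state would leave rare
frames where the chain has opened but the OU distance has not yet relaxed
past 5 Å, breaking the guarantee for no modelling benefit.

**Waters.**  N = 958 points hop with per-axis Gaussian steps (SD 1 Å) in
a periodic box (x ∈ [−6, 36], y, z ∈ [−6, 6] Å) enclosing the tunnel.
Uniform initialisation plus wrapped Gaussian steps keeps the stationary
density exactly uniform, so the expected in-tunnel count is
N·V_tunnel/V_box ≈ 280 for the default 30 Å × 4 Å tunnel — the census
magnitude the analysis should report — with binomial frame-to-frame
fluctuation spanning roughly 250–315.

**Protein.**  Backbone scaffolds (N, CA, C, O per residue) for eight
residue segments placed around the tunnel, each fluctuating as iid
isotropic Gaussian displacement with a per-residue σ: tunnel-lining
helices 373–385 and 824–842 at σ = 0.3 Å (RMSF = σ√3 ≈ 0.52 Å, below
1 Å), loops at 0.5–0.6 Å, and a C-terminal lid at 1.2 Å.  Three
side-chain atoms are placed deterministically: Glu225 CD (anchor),
Arg488 CZ at exactly the simulated gate distance from it, and Arg312 NZ
at the docking site, so the trajectory-level gate and docking analyses
recover the generator's series exactly.

**Ground truth.**  Labels are derived from the *emitted* coordinates with
the same debounced definitions the analysis documents (release: ligand
displacement ≥ 10 Å for 10 consecutive frames; dissociation: minimum
ligand–protein heavy-atom distance > 5 Å for 10 consecutive frames), via
an independent plain-scan code path.  Exact agreement between
`ensemble_outcomes` and the ground truth is therefore a check that the
detectors implement their definitions correctly, not a statistical claim.
Replicates draw from child streams spawned with numpy's counter-based
`SeedSequence`, so ensembles are bitwise reproducible per seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: force-field physics and solvent structure;
ligand internal conformational change; correlated protein motions and
drift (fluctuations are iid, so superposition is near-identity by
construction); gate kinetics beyond two states; any 3-D unbinding pathway
(dissociation is modelled along the tunnel coordinate only); and the
irregular shape of the real tunnel (the census region is an explicit
union of spheres, so absolute water counts transfer to real data only up
to the region definition).

## Analysis definitions and numerical choices

- **Displacement** uses ligand heavy atoms without internal refitting, so
  rotation in place contributes.  Zone bins are half-open: active site
  [0, 10), tunnel [10, 30), distal [30, ∞) Å.
- **Release** is the first frame of a ≥ 10-frame (10 ns) run at
  displacement ≥ 10 Å; the debounce suppresses boundary flicker.
  Increasing the persistence window never yields an earlier release.
- **Dissociation** is the first frame of a ≥ 10-frame run with the
  minimum ligand–protein heavy-atom distance > 5 Å (beyond direct-contact
  range).  A replicate that dissociates is counted only as "dissociated";
  if its threshold crossing precedes the displacement-based release (it
  cannot, in practice), the release frame is clamped to it so event
  records stay ordered.
- **Gate states** are a total function of distance with half-open bins
  [0, 5), [5, 8), [8, ∞) Å; the descriptive upper bound of ~18 Å seen in
  open-state distributions is not a bin edge.  "Open at release" is
  operationalised as *not closed* (≥ 5 Å).  Long-lived open episodes
  default to ≥ 10 Å sustained ≥ 500 ns.
- **Superposition** is a per-frame Kabsch fit to frame 0; the default
  selection is the backbone of the tunnel-lining helices (373–385,
  824–842), the low-RMSF anchors.  Synthetic ensembles are emitted in a
  common lab frame, so the recovery analyses run on the raw frames;
  aligning pure-noise frames perturbs ligand coordinates at the 0.01 Å
  level and would make frame-exact comparisons seed-fragile.
- **Tunnel region**: centerline resampled to 1 Å stations; membership is
  union-of-spheres (within the station radius of ≥ 1 station), which a
  brute-force oracle reproduces exactly.  Default uniform radius 4 Å —
  a typical channel-radius scale, configurable per station.  The
  channeling coordinate of a point is the arc length of its clamped
  segment projection.
- **Docking contact** is Arg312 NZ versus the ligand carboxylate carbon
  at < 5 Å; the carboxylate carbon is this package's convention for the
  P5C "carbonyl" carbon (the iminium C5 is the defensible alternative).
- **RMSF** is referenced to the time-averaged structure (not frame 0),
  backbone = N, CA, C, O; ensemble profiles average per-replicate RMSF
  values rather than pooling displacements.
- **Inter-site separation** is measured FAD N5 ↔ residue-844 nucleophile
  (SG, or OG in a C844S variant) — a convention of this package, since
  depositors do not name the atom pair.
- **Altlocs** resolve to the highest-occupancy conformer (ties by altloc
  identifier); disordered or truncated side chains raise errors rather
  than being imputed.  Histogram bins are half-open with width 0.5 Å by
  default; all counts are conserved under conditioning partitions.
- **Butterfly bend** is the angle between total-least-squares (SVD) plane
  normals of the outer rings {N1, C2, N3, C4, C4X, C10} and
  {C5X, C6, C7, C8, C9, C9A} (C4A/C5A naming variants accepted), folded
  into [0°, 90°]; a planar flavin gives 0° and a construction folded by θ
  about the N5–N10 axis measures exactly θ.  Convexity sign is not part
  of the angle.

## Problem sizes

The default ensemble (21 × 2000 frames, ~960 waters, ~530 protein atoms)
generates in ~25 s and analyses end-to-end in under a minute on one CPU;
the test suite uses a 6 × 1000 ensemble for cross-module checks and the
full default ensemble for the recovery tests.  These sizes are the
package's chosen desk-scale study conditions.

## Known limitations

Event exactness holds because generator truth and detectors share the
same debounced definitions on the same emitted coordinates; on real MD
data there is no ground truth and the persistence window (10 ns) becomes
a genuine tuning parameter.  Docking-residence magnitudes from the
generator (tens of ns) are shorter than what strongly coordinated ion
pairs can show in real simulations; only their detection, not their
magnitude, is validated.  Absolute water counts depend entirely on the
tunnel-region definition.  The geometry metrics assume standard PDB atom
nomenclature for the flavin and amino acids.
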