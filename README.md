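# mechbond

Mechano-regulation analysis of receptor–ligand complexes from molecular
dynamics trajectories: interface-bond occupancy, an independent-bond
dissociation-probability model, force-response classification of individual
bonds, and structural mechano-metrics.

The package was built around the Mac-1 (integrin α_M I-domain) / platelet
GPIbα complex — a leukocyte–platelet adhesion pair whose force response
follows a catch–slip transition — but every stage works on any two-chain
complex.

## What it computes

Given trajectory frames of a two-chain complex, `mechbond` detects interface
hydrogen bonds (donor–acceptor distance < 3.5 Å and D-H···A deviation < 30°)
and salt bridges (acidic side-chain O to basic side-chain N within 4 Å), and
scores each bond's **occupancy** ω — the fraction of frames in which it is
formed.

Treating each bond's survival as an independent event, the occupancies
propagate to residue- and complex-level binding statistics:

- pair probability: p_ij = 1 − Π_l (1 − ω_ij,l) over the M_ij bonds of a
  residue pair,
- per-residue binding: P_j,L = 1 − Π_i (1 − p_ji) (and P_j,R on the other
  side),
- complex dissociation: **P_D = Π_bonds (1 − ω) = Π_j (1 − P_j,L) =
  Π_j (1 − P_j,R)** — the probability that no interface bond survives,
- normalized dissociation: **f_D = P_D(f) / P_D(0)** across tensile-force
  conditions (the mechano-regulation factor).

Around this core sit the standard mechano-metrics (superposed Cα-RMSD,
Shrake–Rupley SASA and buried interface area, inter-helix angle θ,
loop-to-body centroid distance L_MB), per-bond occupancy-vs-force
classification into slip / catch-slip / slip-catch-slip / catch-slip-catch
types, rupture-force extraction from ramp pulling traces, AFM bond-lifetime
binning (7.5 pN bins) and a two-pathway catch–slip off-rate fit, and
synthetic-data generators with exact ground truth for every input kind.

## Worked example

The bundled datasets carry the published interface H-bond occupancies of the
Mac-1/GPIbα docking models and of the force panel (0/25/50/75 pN clamps):

```python
>>> from mechbond.datasets import load_force_panel
>>> from mechbond import DissociationModel
>>> res = DissociationModel(load_force_panel()).fit()
>>> print(res.summary())
Dissociation probability model (independent-bond product form)
reference condition: 0

   condition  n_bonds   sum(w)          P_D        f_D
           0       11    4.440     0.001549          1
          25       11    5.830    9.214e-05    0.05947
          50       11    5.530    0.0001658      0.107
          75       11    4.220     0.003064      1.978
```

Reading: at 25 pN the expected number of simultaneously formed interface
bonds (Σω) rises from 4.44 to 5.83 and the dissociation probability drops
~17-fold (f_D ≈ 0.059) — force *strengthens* the interface; past that
threshold the trend reverses and by 75 pN dissociation is ~2× the unloaded
value. The minimum of f_D (and maximum of Σω) at 25 pN is the catch–slip
transition force. Classifying each bond's occupancy trend:

```python
>>> from mechbond import classify_table
>>> classify_table(load_force_panel()).pattern.value_counts()
pattern
catch-slip          6
slip                2
slip-catch-slip     2
catch-slip-catch    1
```

The same objects run from the shell:

```bash
mechbond analyze complex.pdb --out results/        # one trajectory
mechbond panel --config panel.yaml --out results/  # multi-force panel
```

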