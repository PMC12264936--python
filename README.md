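# vligand — virtual-ligand screening for phosphine selection

`vligand` implements a *virtual ligand* (VL) workflow for picking promising
monodentate phosphine ligands for transition-metal catalysis before running a
single per-ligand quantum-chemistry calculation on the reaction of interest.

## The scientific problem

Optimizing a phosphine ligand PR3 for a reaction usually means computing the
reaction energetics once per candidate ligand — dozens of expensive
calculations, most of them wasted on poor candidates. The VL idea inverts
this: replace the real substituents R by a *model* ligand PCl\*3 whose
electronic and steric character is controlled by three continuous parameters

* `r0` — equilibrium P–Cl\* distance (Å), the main electronic knob,
* `a1` — width of an ovoid steric wall around each Cl\* (Å),
* `b1` — thickness of that wall (Å),

so the objective of interest (a reaction energy or barrier, `y`) becomes a
smooth function `y(p)` of `p = (r0, a1, b1)` that can be **minimized by a
gradient-based optimizer** instead of enumerated. Real ligands are then
mapped into the same parameter space and ranked by how close they land to
the optimum `p*`.

The model ligand is realized through three penalty terms added to the
system's energy:

```
E_keep  = k_keep  * Σ_i (|P - Cl*_i| - r0)^2          (holds P–Cl* at r0)
E_angle = k_angle * Σ_{i<j} (θ_ij - φ0)^2             (holds Cl*–P–Cl* at φ0)
E_ovoid = ε * Σ_{i, env} (ρ^-12 - 2 ρ^-6)             (steric wall)
```

where `ρ` is an elliptical distance from each environment atom to an ovoid
surface of half-axes `(a1, b1)` centered a fixed distance `d` out along each
P–Cl\* axis. All three terms have exact analytic gradients (the ovoid via
forward-mode dual-number differentiation in `vligand._jet`).

The full pipeline:

1. **Descriptors** — each ligand is characterized by its dissociation
   energies against a fixed panel of 16 fragments; PCA compresses these to a
   descriptor vector `x`.
2. **Projection `H`** — the VL parameters trace a 3-parameter surface
   `G(p)` in descriptor space; each real ligand is projected onto it,
   `p = argmin_p ||x − G(p)||`, and the residual `l_min` measures how well
   the VL can represent that ligand at all.
3. **VL-assisted optimization (VLAO)** — conjugate-gradient minimization of
   `y(p)` plus a smooth quartic barrier confining `p` to a physical range;
   the trajectory and the Hessian at the optimum are recorded.
4. **Surrogates** — the objective at a real ligand's `p` is predicted by a
   second-order Taylor model at `p*` (with the Hessian clipped to positive
   semidefinite), by a distance-weighted average of Taylor models along the
   whole trajectory, or directly from the backend.
5. **Reliability filtering and ranking** — ligands with `l_min < 2.0` and
   range-normalized deviation `||Δp'|| < 0.75` (strict; `2.5`/`1.0` loose)
   get trustworthy predictions and are ranked best-first; the rest are
   flagged, not silently mis-ranked.

The package ships a database of 21 phosphine ligands with fitted VL
parameters and reliability residuals (`vligand.descriptors.builtin_ligand_db`),
plus a fully synthetic energy backend so the entire pipeline runs in seconds
on a laptop. Coupling to a real quantum-chemistry backend is a matter of
implementing the two-method backend interface (`eval_objective`,
`eval_descriptors`).

## Worked example

Create `example.yaml`:

```yaml
seed: 7
outdir: example_run
mode: full
sense: minimize
surrogate:
  mode: weighted
backend:
  n: 3
  m: 16
  bump_amplitude: 2.0
  center: [1.5, 2.6, 2.1]
  offset: -25.0
bounds:
  lower: [1.3, 2.0, 1.5]
  upper: [1.9, 3.5, 3.0]
database:
  source: builtin
```

and run the full pipeline:

```
$ vligand run --config example.yaml
ligands: 21
sense: minimize
filter strict (l_min < 2.0, ||dp'|| < 0.75): 6 ligands; top: L20, L10, L12, L18, L11
filter loose (l_min < 2.5, ||dp'|| < 1.0): 11 ligands; top: L19, L20, L10, L12, L18
```

with progress on stderr:

```
INFO vligand: version=0.1.0 config=example.yaml sha256=cc969f0dfec9 seed=7
INFO vligand: pipeline start: version=0.1.0 mode=full seed=7
INFO vligand: stage database: 21 ligands
INFO vligand: stage vlao: 24 iterations, objective -23.0035
INFO vligand: stage rank: counts {'strict': 6, 'loose': 11}
```

The optimizer found `p* = (1.5286, 2.6177, 2.1150)` with objective
−23.0035 (see `example_run/trajectory.json`); the per-ligand report lands in
`example_run/ranking.csv`:

```
id,name,predicted,l_min,dp_norm,pass_strict,rank_strict,pass_loose,rank_loose
L1,P(3;5-diCF3C6H3)3,6.5849067991173991,3.968,1.2993252116384553,False,,False,
L2,P(C6F5)3,-19.172239715124626,2.2610000000000001,0.69793780285532214,False,,True,11
L3,P(CCl3)3,-22.010496039055919,3.3300000000000001,0.77112983999184093,False,,False,
...
```

L1 is excluded by both filters: its residual `l_min = 3.97` says the VL
model cannot represent it, so any prediction for it would be untrustworthy.
The same stages are available individually as `vligand build-db`,
`vligand project`, `vligand vlao`, `vligand predict` and `vligand rank`
(every command takes `--config` and `--seed`).

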