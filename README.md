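# chromopull

Analysis of single-molecule force spectroscopy on large, heterogeneous
chromatin fibers — the kind produced by reconstituting hundreds of
nucleosomes on lambda-phage or native genomic DNA and stretching them one
tether at a time in (multiplexed) magnetic tweezers.

It is written for the experimentalist who has force–extension traces of
nucleosome arrays and wants, per tether: how many nucleosomes are loaded,
how many participate in fiber folding, the fiber's mechanical parameters,
and a census of the large rupture events that signal contacts between
distant nucleosome clusters. Because raw tweezers datasets are rarely
shared, the package includes a seeded synthetic-trace generator with full
ground truth, so the entire pipeline is testable end to end without
laboratory data.

## The model

Bare DNA follows the extensible worm-like chain. Above ~1 pN,

```
z/L = 1 − ½√(kBT/(F·Lp)) + F/S
```

with persistence length `Lp ≈ 50 nm`, stretch modulus `S ≈ 1500 pN` and
0.34 nm per bp; below 1 pN the Marko–Siggia interpolation is solved
numerically.

Each nucleosome is an independent two-tier system. Stacked in the folded
fiber it sequesters one nucleosome repeat length (NRL) of DNA, and the
folded domain stretches as a Hookean spring of stiffness `k_fiber`.
Unstacking plus partial unwrapping to 92 bp wrapped costs `ΔG1` (kT);
further unwinding to 79 bp (13 bp more) costs `ΔG2`. State occupancies are
Boltzmann-weighted with the work term `F·Δz_i(F)`, which produces the
characteristic unfolding plateau at 2–5 pN. The irreversible release of
the last DNA turn (25–27 nm steps above 10 pN) is outside the equilibrium
model and is treated as discrete events.

Per-trace inference follows the two-window counting recipe: `N_total` from
a WLC fit at 8–15 pN with contour reduced by `79 bp × N_total`, `N_folded`
from 0.5–2 pN with contour reduced by `NRL × N_folded` (plus the 92 bp
wrapped by each unfolded nucleosome), then a least-squares fit of
(`k_fiber`, `ΔG1`, `ΔG2`) over 0.3–10 pN with rupture segments masked.

Cluster–cluster ruptures are detected per the published recipe: 15-point
median filter, steps larger than the 68 nm equivalent of 200 bp between
consecutive samples, joining of candidates closer than 5 points, a closed
1–15 pN force window, discarding events with lateral bead displacement
`dR > 0.1 µm`, and an 8 pN cutoff separating cluster–cluster ruptures from
last-turn unwrapping. Rates are normalized to events per 10 kbp of
template.

## Worked example

```python
import chromopull as cp

wlc = cp.WLCParams(contour_bp=48_502)

# a half-saturated lambda fiber: 125 nucleosomes, 49 of them folded
fiber = cp.generate_trace(cp.FiberSpec(n_octamers=125, seed=3))
res = cp.analyze_trace(fiber, wlc, NRL_bp=197.0)
print(res.N_total, res.N_folded, cp.folded_fraction(res.N_folded, res.N_total))
print(round(res.k_fiber, 3), round(res.dG1_kT, 2), round(res.dG2_kT, 2))

# the same fiber with three embedded chromatin-loop ruptures
loopy = cp.generate_trace(cp.FiberSpec(n_octamers=125, seed=7,
        loops=((400, 3.0), (1000, 5.0), (2500, 12.0))))
for ev in cp.analyze_trace_ruptures(loopy, wlc):
    print(ev.klass, round(ev.rupture_force, 2), round(ev.step_bp))
```

prints

```
125 49 39
0.243 20.0 4.49
low 2.99 393
low 5.0 1006
high 11.98 2447
```

i.e. the counts are recovered exactly (39 % folded), the fitted stiffness
and free energies land on the generator truth (0.25 pN/nm, 20 kT, 4.5 kT)
to within a few percent, and the three embedded loop releases are detected
at their rupture forces with sizes within a few percent — the 12 pN event
lands in the `high` class that the 8 pN cutoff excludes from
cluster–cluster rate statistics. (Stiffness fits are quantitative on
rupture-free traces; a large loop closed across the fit window biases `k`,
as it does on real data — see `docs/methods.md`.)

The same pipeline is scriptable from the shell:

```sh
chromopull simulate -n 20 --seed 1 -o cohort/
chromopull fit --traces cohort/ -o fits.csv
chromopull ruptures --traces cohort/ -o cohort_rup
chromopull summarize --results fits.csv -o summary.csv
```

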