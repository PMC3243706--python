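# mtsheet

Coarse-grained mechanochemical simulation of microtubule growth through
the sheet-to-tube transition.

Growing microtubules do not extend as blunt cylinders: cryo-EM shows an
open, outward-curved **sheet** at the plus end that later zips shut along
the **seam**, converting longitudinal curvature into the circumferential
curvature of the closed wall.  This *conformational cap* is thought to
stabilise growth alongside the classical GTP cap.  `mtsheet` implements a
particle-level model of this process for structural biophysicists who
want to probe the energetics of the sheet-to-tube transition: one point
mass per tubulin monomer on the 13-protofilament, 3-start helical
lattice, seven harmonic-class interactions

E = Σ ½k·(Δr)² (longitudinal / lateral / diagonal stretch)
  + Σ ½k·(θ−θ₀)² (longitudinal / lateral bend)
  + Σ ½k·sin²φ (longitudinal / lateral dihedral twist),

with nucleotide-dependent intrinsic curvature (θ₀ = 5° for GTP-, 18° for
GDP-tubulin; lateral rest angle 0° — flat sheets are preferred, so the
closed wall stores elastic energy).  Growth is a chain of discrete
events, each followed by velocity-Verlet relaxation to equilibrium:

* **assembly** — a GTP dimer joins a protofilament tip when the relaxed
  mechanical strain plus the association free energy (−16/−12/−8 k_BT
  for gap/side/crest sites) is negative, with Boltzmann-weighted site
  selection;
* **closure** — the lowest open seam pair acquires its lateral
  interactions; the relaxation transient is the activation barrier, the
  equilibrium shift the energy stepping;
* **hydrolysis** — forced GTP→GDP rules (synchronous with closure,
  ordered caps, or random per tubulin).

See `docs/methods.md` for the full model description, numerical choices,
and a frank account of which published observations this implementation
does and does not reproduce.

## Worked example

Form-find the standard sheet-ended microtubule (30-monomer hydrolyzed
body per protofilament + ten-monomer GTP sheet, 520 monomers) and zip
three seam pairs:

```python
from mtsheet import ModelParams
from mtsheet.growth import prepare_sheet_state, run_closure_sequence

params = ModelParams()
state = prepare_sheet_state(params)          # form-finding, ~10 s
print(f"E0 = {state.e0 / params.kBT_internal:.0f} kBT")
result, _ = run_closure_sequence(params, 3, state=state)
for i, (b, s) in enumerate(zip(result.barriers, result.steppings)):
    print(f"closure {i}: barrier {b:7.0f} kBT   stepping {s:5.0f} kBT")
```

prints

```
E0 = 100539 kBT
closure 0: barrier   51979 kBT   stepping  2998 kBT
closure 1: barrier   56378 kBT   stepping  2996 kBT
closure 2: barrier   55941 kBT   stepping  2744 kBT
```

The equilibrium energy is dominated by lateral bending — the curvature
energy stored in the closed wall.  Each closure costs a transient
activation barrier and steps the lattice energy up by ≈3×10³ k_BT: the
sheet-to-tube transition pumps elastic energy into the wall, which is
the mechanical reservoir released during later depolymerisation.  The
closures are mutually uniform (≈8%), so zipping propagates steadily.

The same experiments are available from the shell:

```bash
mtsheet simulate --closures 3 --out run/           # closure sequence
mtsheet sweep --lengths 1,2,3,4,5,6,7,8,9,10       # cap-length sweep
mtsheet sensitivity --constant k_diag_stretch
mtsheet tetris --layers 2 --seed 7                 # fill-then-zip growth
mtsheet replay run/manifest.yaml                   # bit-identical re-run
```

Each run directory contains CSV tables, energy-trace plots, extended-XYZ
/ PDB snapshots and a manifest that `mtsheet replay` consumes.

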