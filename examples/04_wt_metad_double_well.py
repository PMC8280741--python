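"""Well-tempered metadynamics on a double well vs. the quadrature oracle.

Runs biased dynamics on an asymmetric double well (the 1D coordinate plays
the role of the path progress s), reconstructs the free-energy profile from
the deposited hills, and compares the well-to-well free-energy difference
with exact Boltzmann quadrature.
"""

import math

import numpy as np

from pathmetad import (
    IdentityCVMapping,
    LangevinParams,
    WTParams,
    double_well_free_energy_difference,
    make_double_well,
    project_fes_1d,
    reconstruct_fes,
    run_wt_metad,
)
from pathmetad.units import kbt

surf = make_double_well(barrier=5.0, separation=4.0, asymmetry=2.0)
lo, hi = surf.domain_bounds[0]
grid = (np.linspace(lo, hi, 400), np.array([0.0]))

run = run_wt_metad(surf, IdentityCVMapping(),
                   WTParams(sigma_s=0.2, sigma_z=0.7), walls=None,
                   langevin=LangevinParams(seed=3), n_steps=500_000,
                   grid=grid)
profile = project_fes_1d(reconstruct_fes(run.hills, grid))

kT = kbt(300.0)
top = surf.metadata["barrier_top"]
mask = profile.s < top
za = np.trapezoid(np.exp(-profile.F[mask] / kT), profile.s[mask])
zb = np.trapezoid(np.exp(-profile.F[~mask] / kT), profile.s[~mask])
estimate = -kT * math.log(zb / za)
oracle = double_well_free_energy_difference(surf, 300.0)

print(f"hills deposited: {len(run.hills)} "
      f"(first {run.hills[0].height:.3f}, last {run.hills[-1].height:.3f} kcal/mol)")
print(f"well-to-well dF  estimated: {estimate:+.3f} kcal/mol")
print(f"well-to-well dF  exact:     {oracle:+.3f} kcal/mol")
print("the decaying hill heights show the well-tempered bias converging; "
      "the estimate should sit within a few tenths of the exact value.")
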