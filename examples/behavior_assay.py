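"""Stimulus-response readouts for a responsive vs an impaired group.

Simulates plate-assay trajectories for two groups of 50 larvae — one
with a strong per-frame avoidance probability, one with a weak one and
reduced swim speed — then computes the percent-down occupancy and mean
swim speed for each.
"""

import zfquant as zq

groups = {
    "control": zq.SyntheticBehaviorParams(p_avoid=0.8, seed=23),
    "impaired": zq.SyntheticBehaviorParams(p_avoid=0.1,
                                           baseline_speed_mm_s=1.0, seed=24),
}

for name, params in groups.items():
    traj, truth = zq.generate_behavior(params)
    metrics = zq.behavior_metrics(traj)
    print(f"{name:9s} true p_avoid={truth.p_avoid:.1f}  "
          f"percent_down={metrics.percent_down:5.1f}%  "
          f"mean speed={metrics.mean_speed_mm_s:.2f} mm/s  "
          f"(n={metrics.n_larvae})")

print()
print("percent_down is the time-averaged share of larvae in the trough")
print("half away from the animated bar; ~50% means no response, values")
print("near 100% mean strong avoidance.")
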