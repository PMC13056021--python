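"""Egocentric encoding of a conspecific by a hippocampal neuron.

Simulates a 30-minute session of five bats on the large net plus a neuron
whose firing follows von Mises direction tuning (preferred bearing 45 deg
left of ahead, kappa = 4) and Gaussian distance tuning (preferred 0.30 m)
toward bat B.  The analysis then: (1) classifies the neuron egocentric vs
allocentric by DIC, (2) attributes its explained deviance across all
angle/distance variables with exact Shapley values, and (3) extracts the
empirical tuning curves of the top-attributed bat.
"""

from batcolony import encoding, synthetic

colony = synthetic.make_colony(5, seed=0)
traj = synthetic.simulate_trajectories(
    colony, seed=7, duration=1800, frame_rate=10,
    large_net_prob=1.0, flight_mean=2.0,
)
spec = synthetic.TuningSpec("cell-01", host="A", target="B", mode="egocentric")
spikes = synthetic.simulate_spike_train(traj, spec, seed=8)

frame = encoding.build_covariates(traj, "A")
counts = frame.count_spikes(spikes)
ok, summary = encoding.inclusion_filter(spikes, frame)
print(f"inclusion: {ok} ({summary['qualifying_seconds']:.0f} s qualifying, "
      f"{summary['qualifying_spikes']:.0f} spikes)")

cls = encoding.classify_neuron(frame, counts)
print(f"classification: {cls.label} (dDIC = DIC_allo - DIC_ego = "
      f"{cls.delta_dic:+.1f}; threshold |dDIC| > 10)")

attr = encoding.shapley_attribution(frame, counts)
print("\nShapley explained-deviance shares:")
for (kind, bat), phi in zip(attr.variables, attr.phi):
    print(f"  {kind:5s} -> bat {bat}: {phi:+.4f}")
print(f"top encoded angle: bat {attr.top_angle_bat}; "
      f"top encoded distance: bat {attr.top_distance_bat}")

tc_a = encoding.tuning_curve(frame, counts, attr.top_angle_bat, "angle")
tc_d = encoding.tuning_curve(frame, counts, attr.top_distance_bat, "distance")
print(f"\npreferred angle:    {tc_a.preferred:+.0f} deg (generative: "
      f"{spec.preferred_angle:+.0f} deg)")
print(f"preferred distance: {tc_d.preferred:.2f} m (generative: "
      f"{spec.preferred_distance:.2f} m)")
print()
print(
    "The neuron should classify egocentric with the Shapley mass on bat\n"
    "B's angle/distance variables, and the tuning-curve peaks should land\n"
    "within one bin of the generative parameters."
)
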