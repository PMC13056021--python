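"""Hierarchy-linked behavior: food monopolization and sleep arrangements.

Part 1 - food: sessions where the latent rank drives food-bowl visits;
each bat's normalized share of bowl time is correlated with its Elo rating.

Part 2 - sleep: light-phase huddle sessions where the top- and bottom-
ranked bats sit interior to the sleeping cluster; the convex-hull analysis
recovers who slept in the middle versus on the periphery.
"""

import warnings

from batcolony import behavior, dominance, synthetic

warnings.filterwarnings("ignore")

colony = synthetic.make_colony(5, seed=11)
races = synthetic.simulate_races(colony.latent_rank, weeks=30, slope=5.0, seed=1)
elo = dominance.elo_ratings(races)

occs = []
for s in range(4):
    traj = synthetic.simulate_trajectories(
        colony, seed=40 + s, duration=1800, frame_rate=5,
        bowl_rate_per_hour=12.0, bowl_rank_gain=4.0,
    )
    occs.append(behavior.food_occupancy(traj))

rep = behavior.hierarchy_food_correlation(occs, elo)
r = rep["time_pearson"]
print(f"Elo vs normalized bowl time: Pearson r = {r.statistic:.2f} "
      f"(p = {r.p_value:.2g}, n = {r.n} session x bat rows)")

top, bottom = elo.rank_order()[0], elo.rank_order()[-1]
nights = [
    behavior.middle_periphery(
        synthetic.simulate_sleep_session(colony, {top, bottom}, seed=60 + k,
                                         duration=600),
        elo=elo,
    )
    for k in range(5)
]
res = behavior.sleep_rank_test(nights)
print("\nmean middle-fraction by hierarchy class over 5 nights:")
for cls in ("top", "intermediate", "bottom"):
    s = res["summary"][cls]
    print(f"  {cls:13s}: {s['mean']:.2f} (n={s['n']})")
p = res["top_vs_intermediate"].p_value
print(f"top vs intermediate rank-sum p (Bonferroni x2): {p:.3g}")
print()
print(
    "A positive food correlation means higher-ranked bats monopolize the\n"
    "bowl; middle-fraction near 1 for the top and bottom ranked bats and 0\n"
    "for intermediates reproduces the extremes-sleep-inside pattern."
)
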