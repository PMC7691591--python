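"""Cohort-level endpoint comparison with exact small-sample statistics.

Simulates the default 5 TD + 7 NTD cohort, computes the seven
per-session endpoints, and prints the comparison table (exact Wilcoxon
rank-sum W and p, BH-adjusted p, pooled-SD effect size).
"""

import homebase as hb

room = hb.default_room()
cohort = hb.simulate_cohort(seed=1, room=room)
sessions = [(s.session_id, s.group, s.trajectory) for s in cohort.sessions]
bundle = hb.run_pipeline(sessions, room, hb.RunConfig(compute_maps=False))

print(bundle["comparison"].round(4).to_string(index=False))

row = {r.endpoint: r for r in bundle["comparison_rows"]}["excursions_per_min"]
print(f"\nexcursion rate: W = {row.w_statistic:.0f}, exact p = {row.p_value:.5f}")
# W = 35 is the maximal rank-sum statistic at n = (5, 7): every TD
# session out-ranks every NTD session (complete separation), and the
# exact two-sided p is 2/792 ~ 0.00253.
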