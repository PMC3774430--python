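"""Reproduce the national industry prioritization from the published statistics.

Uses the 25 published per-industry EHI statistics (95th percentile of
the enterprise scores in each industry) and assigns the four control
priority bands from the 90th/70th/50th percentile cutoffs.
"""

from ehi import assign_priorities, distribution_stats, percentile
from ehi import reference as ref
from ehi.scoring import IndustrySummary

summaries = [
    IndustrySummary(code, name, n, value)
    for code, name, n, value in ref.NATIONAL_INDUSTRIES
]
values = [s.statistic for s in summaries]

mean, sd = distribution_stats(values)
print(f"industry EHI distribution: mean {mean:.1f}, SD {sd:.1f} over {len(values)} industries")

pa = assign_priorities(summaries)
p90, p70, p50 = pa.cutoffs
print(f"cutoffs: p90={p90:.2f}  p70={p70:.2f}  p50={p50:.2f}")
print(f"band sizes (priority 1..4): {pa.band_sizes()}")

for s in sorted(summaries, key=lambda s: -s.statistic):
    print(f"  band {pa.bands[s.industry_code]}  {s.statistic:6.2f}  {s.industry_name} (n={s.n_enterprises})")
# Band 1 industries (statistic >= p90) are first in line for national
# exposure-control resources; a statistic exactly at a cutoff takes the
# higher band.
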