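"""Weekly trend series, overall percentages, and trend correlations."""

from vaxsent import (
    CorpusConfig,
    cross_platform_average,
    generate_corpus,
    overall_proportions,
    posts_to_frame,
    trend_strength,
    weekly_proportions,
)
from vaxsent.trends import get_series

records, labels = generate_corpus(CorpusConfig(n_posts=10_000, seed=3))
truth = {t.post_id: int(t.label) for t in labels}
labeled = posts_to_frame(records).assign(label=[truth[r.id] for r in records])

weekly = weekly_proportions(labeled)
pos_gb_fb = get_series(weekly, "GB", "facebook", "positive")
print(f"GB/Facebook positive series: {len(pos_gb_fb)} weeks")
print(f"trend strength r = {trend_strength(pos_gb_fb):.3f} "
      "(sign = direction, magnitude = strength of the weekly trend)")

overall = overall_proportions(labeled)
print("\noverall percentages by platform:")
print(overall.to_string(index=False))

for country in ("GB", "US"):
    sub = labeled[labeled["country"] == country]
    per_platform = {
        p: dict(zip(g["class"], g["percent"]))
        for p, g in overall_proportions(sub).groupby("platform")
    }
    avg = cross_platform_average(per_platform)
    print(f"\n{country} cross-platform average (unweighted platform mean):", avg)
# The cross-platform negative share sits between the two platform values;
# the unweighted mean is the aggregation that reproduces published
# overall-vs-per-platform figures.
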