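"""N-gram mining per sentiment class and region-level sentiment maps."""

import json

from vaxsent import (
    CorpusConfig,
    attach_geojson,
    clean_corpus,
    generate_corpus,
    ngram_counts,
    posts_to_frame,
    region_sentiment,
    top_terms,
)

records, labels = generate_corpus(CorpusConfig(n_posts=8000, seed=19))
truth = {t.post_id: int(t.label) for t in labels}

# top unigrams in negative posts only (word-cloud backing table)
negative = [r for r in records if truth[r.id] == -1]
table = top_terms(ngram_counts(clean_corpus(negative), 1, scope="negative"), 5)
print("top tokens in negative posts:")
print(table.to_frame().to_string(index=False))

# region-level mean sentiment on the -1..+1 scale (+1 green, -1 red)
labeled = posts_to_frame(records).assign(
    label=[truth[r.id] for r in records], combined=0.0
)
result = region_sentiment(labeled, min_posts=10)
print("\nregion means (label average = (n_pos - n_neg) / n):")
print(result.table.to_string(index=False))

# join onto user-supplied region geometry for choropleth rendering
geometry = {
    "type": "FeatureCollection",
    "features": [
        {"type": "Feature", "properties": {"region": "Cornwall"}, "geometry": None},
        {"type": "Feature", "properties": {"region": "Texas"}, "geometry": None},
    ],
}
geo = attach_geojson(result, geometry)
print("\nGeoJSON properties after the join:")
print(json.dumps([f["properties"] for f in geo["features"]], indent=2))
# Regions with planted positive offsets (Cornwall) come out greener than
# those with negative offsets (Texas).
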