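"""Build labeling-priority heatmaps and rank slides by annotation value.

Trains a deliberately under-trained classifier (seed labels only) on a
simulated cohort, grids each slide into 512-px cells, and counts objects
whose normalized vote-margin confidence falls at or below 0.25. Slides
rich in low-confidence objects are where an annotator's next labels help
most.
"""

from histolearn import (
    SimConfig,
    build_heatmap,
    make_seed_labels,
    predict_confidence,
    rank_slides,
    simulate_benchmark,
    train_forest,
)

config = SimConfig(seed=3, n_slides=4, n_objects=3000,
                   positive_prevalence=0.04, validation_per_class=30)
slides, store, truth, _validation = simulate_benchmark(config)
model = train_forest(store, make_seed_labels(truth, seed=3))
pred = predict_confidence(model, store)

heatmaps = [
    build_heatmap(pred, store, meta, cell_size_px=512, threshold_norm=0.25)
    for meta in slides
]
ranking = rank_slides(heatmaps)
print(ranking.to_string(index=False))

top = heatmaps[[h.slide_id for h in heatmaps].index(ranking.slide_id.iloc[0])]
r, c = divmod(int(top.low_confidence_count.argmax()), top.low_confidence_count.shape[1])
print(
    f"\nSlide {top.slide_id} has the highest fraction of low-confidence objects "
    f"({ranking.frac_low_confidence.iloc[0]:.3f}); its hottest cell is grid "
    f"({r}, {c}) with {top.low_confidence_count[r, c]} uncertain objects out of "
    f"{top.object_count[r, c]} — the region to zoom into and label next."
)
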