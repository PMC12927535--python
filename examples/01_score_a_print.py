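"""Score a synthetic print: four criteria and the overall printability score.

Generates three replicate 4x4 droplet grids (500 µm spacing) with mild
imperfections, classifies droplets against the CAD design, pools the
replicates and prints the indexed score.
"""
import liftqc as lq

design = lq.PatternDesign.grid(4, 4, 500.0)
parts = []
for seed in (1, 2, 3):
    params = lq.SynthPrintParams(
        design=design, transfer_prob=0.95, mean_diameter=75.0, diameter_cv=0.1,
        placement_jitter_sd=5.0, satellite_rate=0.3, pixel_size=5.0, seed=seed,
    )
    mask, record = lq.generate_print(params)
    obs = lq.classify_satellites(lq.observations_from_labels(mask, 5.0), record.design)
    rec = lq.PrintRecord(record.condition, record.design, tuple(obs), 5.0)
    parts.append(lq.compute_print_criteria(rec))

pooled = lq.pool_criteria(parts)
d_ref = lq.compute_reference(pooled.diameter_values)  # 10th-percentile reference
scores = lq.overall_score(pooled, lq.ScoreConfig(diameter_reference=d_ref))

print(f"mains matched        : {pooled.n_main}/{pooled.n_expected}")
print(f"mean diameter        : {pooled.mean_diameter:.1f} µm (d_ref {d_ref:.1f} µm)")
print(f"diameter score       : {scores.diameter_score:.3f}")
print(f"efficiency           : {scores.efficiency_score:.3f}")
print(f"circularity          : {scores.circularity_score:.3f}")
print(f"satellite score      : {scores.satellite_score:.2f}")
print(f"overall score        : {scores.overall:.3f}  (acceptable: {scores.acceptable()})")
# The overall score is the equal-weight mean of the four criteria; above
# 0.5 the condition sits inside the printability window.
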