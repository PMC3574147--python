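"""Infer peak strands from the TSS table and assign functional categories.

The library is unstranded, so strand comes from transcription start sites
mapped under the same growth conditions: a TSS pointing into a peak within
500 bp votes for its strand.  Enriched peaks are then classified as
housekeeping (tRNA/rRNA), sRNA, 5' leader, or one of four ORF-overlap
classes, and tallied.
"""

from ripcall import (
    PipelineConfig,
    SimulationConfig,
    call_peaks,
    classify_peaks,
    compute_coverage,
    filter_enriched,
    generate_annotation,
    score_peaks,
    simulate_reads,
    summarize_categories,
    union_peaks,
)

sim = SimulationConfig(seed=1)
pipe = PipelineConfig()

annotation, tss, truth = generate_annotation(sim)
ip, ctrl = simulate_reads(annotation, truth, sim)
peaks = union_peaks(
    call_peaks(compute_coverage(ip, sim.genome_length), pipe),
    call_peaks(compute_coverage(ctrl, sim.genome_length), pipe),
)
score_peaks(peaks, ip, ctrl, pipe)
enriched, _ = filter_enriched(peaks, pipe)
classify_peaks(enriched, annotation, tss, pipe)

summary = summarize_categories(enriched, pipe)
print(summary.by_category.to_string(index=False))
print()
print("each enriched peak gets exactly one category; proportions sum to 1.")
print("sRNA and leader peaks dominate here because those are the region")
print("types the synthetic pull-down enriches")
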