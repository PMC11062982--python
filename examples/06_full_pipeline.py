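"""Run every stage end-to-end and merge the evidence per gene.

One global seed derives per-stage seeds; the toy genome's genes are named
after the regulator analogs the screen's confirmed hits interrupt, so the
final report shows genes supported by several independent lines of evidence
(co-expression consensus, screen phenotype, insertion mapping, qPCR fold).
"""

from pathlib import Path

from azoreg import pipeline as pl

outdir = Path("scratch/example_run")
result = pl.run_pipeline(pl.PipelineConfig(seed=1), outdir)

ev = result.report.evidence
multi = ev[ev["sources"].str.contains(";")]
print(f"evidence rows: {len(ev)}; multi-evidence genes: {len(multi)}")
print(multi.to_string(index=False))
print(f"\noutputs + sha256 checksums in {outdir / 'manifest.json'}")
print("A gene listed with sources like 'mapping;screen;qpcr' is the "
      "pipeline's analog of a confirmed candidate regulator: its disruption "
      "changed decolorization, the insertion mapped inside it, and its "
      "transcription responded to the dye.")
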