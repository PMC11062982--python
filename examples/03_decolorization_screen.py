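"""Score a 4320-clone decolorization screen and confirm its hits.

Each well's azo-dye absorbance drop over 16 h gives a decolorization
percentage; mutants are normalized to their plate's wild-type wells and
classified (<= 65% of WT = reduced, >= 110% = increased). Preliminary hits
are retested (2 experiments x 3 replicates) and confirmed with a Welch
t-test against the wild type.
"""

from azoreg import screen as sc
from azoreg import simulate as sim

cfg = sim.ScreenSimConfig(seed=1)
plates, truth = sim.gen_screen(cfg)
print(f"library: {cfg.n_mutants} mutants on {plates['plate'].nunique()} plates")

scored = sc.score_plates(plates, wt_strain=sim.WT_STRAIN)
called = sc.call_hits(scored)
print("preliminary classes:", called["hit_class"].value_counts().to_dict())

prelim = called[
    (called["hit_class"] != "neutral")
    & (called["strain"] != sim.KO_CONTROL_STRAIN)
]["strain"].tolist()
retest = sim.gen_retest(cfg, truth, prelim, seed=2)
wt_reps = retest[retest["strain"] == sim.WT_STRAIN]["decol_pct"]
conf = sc.confirm_hits(retest[retest["strain"] != sim.WT_STRAIN], wt_reps)
confirmed = conf[conf["confirmed"]]
print(f"confirmed hits: {len(confirmed)} "
      f"({(confirmed['hit_class'] == 'reduced').sum()} reduced, "
      f"{(confirmed['hit_class'] == 'increased').sum()} increased)")

planted = {s for s, c in truth.strain_class.items() if c != "neutral"}
tp = len(set(confirmed["strain"]) & planted)
print(f"planted non-neutral strains: {len(planted)}; recovered: {tp}")
print("\nMost single-well preliminary flags are assay noise (the >=110 "
      "cutoff sits ~1.3 sd above a neutral strain's normalized value); "
      "replicate confirmation removes them while keeping the true effects.")
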