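#!/usr/bin/env python
"""Complete parent-offspring trios from the accepted duos, then the
two-stage grandparent search after masking one genotyped parent."""

import pandas as pd
from _common import RESULTS, THRESHOLDS, load_cohort

import snpedigree as sp
from snpedigree import exclusion
from snpedigree.relatedness import candidate_pairs

RESULTS.mkdir(parents=True, exist_ok=True)
matrix, meta, truth = load_cohort()
run = sp.run_all(matrix, meta,
                 sp.PipelineConfig(thresholds=THRESHOLDS, seed=2024))

present = set(matrix.diploid_ids())
expected = {(c, ps) for c, ps in truth.true_trios()
            if c in present and set(ps) <= present}
accepted = {(t.offspring, frozenset((t.p1, t.p2))) for t in run.trios}
print(f"trios: {len(run.trios)} accepted of "
      f"{run.counts['candidate_trios']} candidates "
      f"(threshold {run.thresholds_realized['trio']} ME)")
print(f"against truth: {len(accepted & expected)}/{len(expected)} true trios "
      f"recovered, {len(accepted - expected)} false")

pd.DataFrame([{"offspring": t.offspring, "p1": t.p1, "p2": t.p2,
               "me": t.me_count, "accepted": t.accepted}
              for t in run.all_trios]).to_csv(RESULTS / "trios.tsv",
                                              sep="\t", index=False)

# grandparent search: delete one genotyped mid-pedigree parent so its
# children lose their trio, then look for the missing parent's parents
target = next(p for c, ps in truth.pedigree.items() for p in ps
              if p in truth.pedigree and truth.generation[p] == 2)
couple = frozenset(truth.pedigree[target])
masked = sp.mask_individuals(matrix, [target])
meta_m = {k: v for k, v in meta.items() if k != target}
run_m = sp.run_all(masked, meta_m,
                   sp.PipelineConfig(thresholds=THRESHOLDS, seed=2024))
print(f"\nmasked parent {target} (its parents: {sorted(couple)})")
print(f"grandparent groups accepted: {len(run_m.gp_groups)} "
      f"(stage thresholds {run_m.thresholds_realized['gp_stage1']} on the "
      f"10% subpanel, {run_m.thresholds_realized['gp_stage2']} full panel)")
for g in run_m.gp_groups:
    ok = frozenset((g.gp1, g.gp2)) == couple
    print(f"  offspring {g.offspring} + parent {g.parent}: couple "
          f"{g.gp1} x {g.gp2} ({g.me_stage1}/{g.me_stage2} ME) "
          f"{'= true couple' if ok else ''}")

pd.DataFrame([{"offspring": g.offspring, "parent": g.parent, "gp1": g.gp1,
               "gp2": g.gp2, "me_stage1": g.me_stage1,
               "me_stage2": g.me_stage2}
              for g in run_m.gp_groups]).to_csv(
    RESULTS / "grandparent_groups.tsv", sep="\t", index=False)
print(f"wrote {RESULTS / 'trios.tsv'}, "
      f"{RESULTS / 'grandparent_groups.tsv'}")
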