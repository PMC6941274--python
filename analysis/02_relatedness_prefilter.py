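#!/usr/bin/env python
"""Pairwise PI_HAT over all diploid pairs: calibration against the truth
pedigree and the >0.4 prefilter that feeds the exclusion tests."""

import itertools

import numpy as np
from _common import RESULTS, THRESHOLDS, load_cohort

from snpedigree.relatedness import (allele_frequencies, candidate_pairs,
                                    pairwise_pi_hat, write_pairs_tsv)

RESULTS.mkdir(parents=True, exist_ok=True)
matrix, meta, truth = load_cohort()

freqs = allele_frequencies(matrix)
ids, pi, _ = pairwise_pi_hat(matrix, freqs)
pos = {i: k for k, i in enumerate(ids)}

po = [pi[pos[c], pos[p]] for c, ps in truth.pedigree.items()
      for p in ps if c in pos and p in pos]
hs = [pi[pos[a], pos[b]] for a, b in map(sorted, truth.half_sib_pairs())
      if a in pos and b in pos]
founders = [i for i in ids if truth.generation[i] == 1]
un = [pi[pos[a], pos[b]] for a, b in itertools.combinations(founders, 2)
      if truth.unrelated(a, b)]
print(f"PI_HAT means (expected 0.5 / 0.25 / 0):")
print(f"  parent-offspring {np.mean(po):.3f} (n={len(po)})")
print(f"  half sibs        {np.mean(hs):.3f} (n={len(hs)})")
print(f"  unrelated        {np.mean(un):.3f} (n={len(un)})")

pairs = candidate_pairs(matrix, freqs, threshold=THRESHOLDS.pi_hat_min)
found = {frozenset((p.id1, p.id2)) for p in pairs}
present = set(matrix.diploid_ids())
truth_po = {p for p in truth.true_duos() if p <= present}
print(f"prefilter PI_HAT > {THRESHOLDS.pi_hat_min}: {len(pairs)} pairs; "
      f"contains {len(found & truth_po)}/{len(truth_po)} true "
      "parent-offspring pairs")
write_pairs_tsv(pairs, RESULTS / "candidate_pairs.tsv")
print(f"wrote {RESULTS / 'candidate_pairs.tsv'}")
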