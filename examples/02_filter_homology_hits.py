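"""Filter a homology-search result and remove redundant candidates.

Parses a BLAST/MMseqs2 tabular (m8) file, keeps hits with E-value < 1e-3
that cover at least 90% of BOTH query and target, then collapses sequences
at >= 90% pairwise identity to one representative — the same candidate-panel
preparation used before ranking.
"""

import tempfile
from pathlib import Path

import numpy as np

from enzrank.homology import filter_hits, parse_hits_m8, redundancy_filter
from enzrank.seqio import SequenceRecord
from enzrank.synthfit import generate_toy_hits

SEED = 4

content, planted_survivors = generate_toy_hits(
    seed=SEED, n=100, frac_fail_evalue=0.2, frac_fail_cov=0.2
)
with tempfile.TemporaryDirectory() as tmp:
    m8 = Path(tmp) / "hits.m8"
    m8.write_text(content)
    hits = parse_hits_m8(m8)

kept = filter_hits(hits, max_evalue=1e-3, min_bidir_cov=0.9)
print(f"parsed {len(hits)} hits; {len(kept)} pass the E-value + coverage filter")
print(f"filter agrees with the planted ground truth: "
      f"{[h.target_id for h in kept] == planted_survivors}")

# redundancy removal on a mutant family: 3 clusters of near-identical copies
rng = np.random.default_rng(SEED)
aa = list("ACDEFGHIKLMNPQRSTVWY")
records = []
for ci in range(3):
    seed_seq = "".join(rng.choice(aa, size=80))
    for k in range(4):
        s = list(seed_seq)
        for pos in rng.choice(80, size=2, replace=False):
            s[pos] = rng.choice([a for a in aa if a != s[pos]])
        records.append(SequenceRecord(f"c{ci}_{k}", "".join(s)))

reps, assignment = redundancy_filter(records, threshold=0.9)
print(f"\n{len(records)} near-duplicate sequences collapse to {len(reps)} representatives:")
for rep in reps:
    members = sorted(i for i, r in assignment.items() if r == rep.id)
    print(f"  {rep.id} <- {members}")
print("each non-representative is >= 90% identical to its representative")
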