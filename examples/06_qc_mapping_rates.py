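"""Mapping-rate QC arithmetic from alignment category counts.

Given per-library counts of reads aligned 0 times, exactly once, and more
than once, the mapped total is (once + multi) and the mapping rate divides
it by all reads that entered alignment.
"""

import pandas as pd

from apakit.qc import mapping_summary

rows = pd.DataFrame(
    [
        {"sample_id": "coty1", "raw_reads": 13_110_749, "low_quality": 166,
         "aligned_0": 4_916_641, "aligned_1": 6_829_234,
         "aligned_multi": 1_208_288},
        {"sample_id": "18TL1", "raw_reads": 7_285_299, "low_quality": 96,
         "aligned_0": 2_917_136, "aligned_1": 3_310_416,
         "aligned_multi": 955_538},
    ]
)
out = mapping_summary(rows)
print(out[["sample_id", "mapped_reads", "mapping_rate_pct"]].to_string(index=False))
# coty1: 8,037,522 mapped reads -> 62.05%; 18TL1: 4,265,954 -> 59.39%
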