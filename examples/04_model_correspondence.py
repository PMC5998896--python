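"""Why a similarity histogram cannot pin down event ploidy.

A duplication-then-triplication parameter point is mapped to a
triplication-then-duplication point with the *same* expected t1-pairs,
t2-pairs and unpaired genes — hence the same likelihood on any
histogram.  Outside a bounded volume no such counterpart exists, and
in the one-parameter (constrained) models the matched points disagree
on unpaired genes: the lever that restores discrimination.
"""

from wgmfrac import (
    DupFirstParams,
    constrained_correspondence,
    dup_first_expectations,
    dup_to_trip,
    trip_first_expectations,
    valid_region_scan,
)

dup = DupFirstParams(u=0.10, v=0.10, w=0.40)
print("dup-first point:", dup)
print("its observable triple (t1 pairs, t2 pairs, unpaired):")
print("  ", tuple(round(x, 6) for x in dup_first_expectations(dup)))

res = dup_to_trip(dup)
for root in res.roots:
    print(f"  root {root.classification}: {root.raw}")
twin = res.valid[0]
print("valid trip-first twin:", twin)
print("its triple:", tuple(round(x, 6) for x in trip_first_expectations(twin)))

scan = valid_region_scan(0.05)
frac = scan.has_counterpart.mean()
print(f"\nshare of the valid (u,v,w) lattice with a trip-first twin: {frac:.1%}")

match = constrained_correspondence(s=0.4, w=0.5)
print(f"\nconstrained models: (s,w)=(0.4,0.5) matches (h,z)=({match.h:.4f}, {match.z:.4f})")
print(f"unpaired-gene disagreement: {match.unpaired_difference:+.4f} per ancestral gene")
print("nonzero disagreement means the observed unpaired count can break the tie")
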