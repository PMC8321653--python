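"""Call fragile-site deletions from copy-number segments.

Builds a tiny three-patient segment table, filters on the segmentation
value (strictly below -0.1) and calls per-patient deletions over one
fragile-site region.
"""

from fragilexpress import (
    GenomicInterval,
    RegionSet,
    SegmentRecord,
    call_deletions,
    filter_segments,
)

site = RegionSet(
    [GenomicInterval("chr4", 90_100_000, 91_600_000, name="FRA4F")],
    kind="fragile_site",
)

segments = [
    # patient P1: focal loss inside the site (log2 ratio -0.6)
    SegmentRecord("P1", GenomicInterval("chr4", 90_500_000, 91_000_000), 400, -0.6),
    # patient P2: shallow dip, above the -0.1 filter -> not a deletion
    SegmentRecord("P2", GenomicInterval("chr4", 90_400_000, 91_200_000), 500, -0.08),
    # patient P3: copy-neutral segment
    SegmentRecord("P3", GenomicInterval("chr4", 90_000_000, 92_000_000), 900, 0.01),
]

filtered = filter_segments(segments)  # keeps seg_mean < -0.1
calls = call_deletions(filtered, site, samples=["P1", "P2", "P3"])

for c in calls:
    print(
        f"{c.sample_id}: deleted={c.deleted}  overlap={c.overlap_bp:,} bp"
        f"  weighted seg value={c.weighted_seg_value}"
    )

# Expected: only P1 is called deleted (500 kb of the site at value -0.6);
# P2's -0.08 segment fails the strict -0.1 filter, P3 is copy-neutral.
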