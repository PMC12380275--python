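"""Parse a genomic region and choose a standardization resolution.

The ~1 Mb TAD on chr1 used throughout the documentation tiles into exactly
214 beads at 5 kb/bead — the common resolution every model is resampled to.
"""

from chrombench import bead_count, parse_region

region = parse_region("chr1:178,421,513-179,491,193")
print(f"region        : {region}")
print(f"length        : {region.length():,} bp")
for bp in (1000, 5000, 10000):
    print(f"{bp:>6} bp/bead : {bead_count(region, bp)} beads")
# The bead counts are what a distance matrix of this region will be sized
# to at each resolution; 5 kb is the default standardization target.
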