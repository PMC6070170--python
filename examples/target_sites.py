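"""Score candidate target sites for a miRNA by position-weighted complementarity.

Penalties accumulate per position from the miRNA 5' end (mismatch 1.0,
G:U wobble 0.5, doubled at positions 2-13); 0 means a perfect complement.
"""

from mirscout import NucSequence, scan_targets, score_site
from mirscout.seqio import reverse_complement

mir = NucSequence("mir", "UGGAGCUCCCUUCAUUCCAAU")

perfect = NucSequence("site", reverse_complement(mir.seq))
print("perfect site      :", score_site(mir, perfect))

seed_mm = list(perfect.seq)
seed_mm[len(mir) - 5] = "A"  # mismatch opposite miRNA position 5 (core, doubled)
print("core mismatch site:", score_site(mir, NucSequence("s", "".join(seed_mm))))

transcript = NucSequence("tx", "GUACGAU" * 30 + perfect.seq + "CAGUCCA" * 30)
hits = scan_targets(mir, [transcript], cutoff=5.0)
for h in hits:
    print(f"hit {h.transcript_id}[{h.start}:{h.end}] expectation={h.expectation} mode={h.mode}")

# The planted perfect site scores 0 (cleavage mode); the core mismatch costs
# 2.0; the scan reports every site at or below the expectation cutoff.
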