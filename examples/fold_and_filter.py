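"""Build one precursor hairpin, fold it and walk through the filter verdicts.

Shows the bundled additive-energy fold (dot-bracket), the mature:star duplex
read off the pairing table, and the per-criterion pass/fail report.
"""

from mirscout import NucSequence, evaluate, extract_duplex, fold, make_precursor

mature = NucSequence("example-mir", "GCAUGCAUGGCAUCCGAUGCAG")
precursor, truth = make_precursor(mature, star_mutations=2, loop_len=6, arm="5p", seed=1)

h = fold(precursor)
print(h.to_vienna(precursor.id))

duplex = extract_duplex(h, truth.mature_span)
print(f"duplex: {duplex.paired_count} pairs, {duplex.mismatches} mismatches, "
      f"bulges={list(duplex.bulges)}")

report = evaluate(precursor, mature, h, mature_span=truth.mature_span)
for name, verdict in report.verdicts.items():
    print(f"  {name:18s} {'pass' if verdict.passed else 'FAIL'}  value={verdict.value}")
print("accepted:", report.accepted, "| stats:", report.stats)

# The dot-bracket shows one stem-loop; the two engineered star mutations
# appear as duplex mismatches (still below the <6 bound), and every criterion
# passes, so the candidate is accepted with its LP/GC/MFE/MFEI statistics.
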