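"""Quantify privacy for every storage x transmission policy.

Per-context privacy is 1 minus a sigmoidal risk membership of the
disclosure percentage (clamped to exactly 1 at 0% and 0 at 100%), and
the storage and transmission dimensions multiply.  The grid below is
the full scenario taxonomy: rows are what is kept locally, columns what
is sent to the care provider.
"""

import dndmotion as dm

store_levels = [0, 30, 100]  # nothing / analytic result / raw data
trans_levels = [0, 10, 30, 100]  # nothing / handshakes / analytic result / raw

grid = dm.scenario_matrix(store_levels, trans_levels)

print("privacy P (1 = fully private, 0 = raw data exposed)")
print("store\\send   none  handshake  report  raw")
for xs, row in zip(store_levels, grid):
    print(f"  {xs:>3}%     " + "  ".join(f"{p:7.3f}" for p in row))

for letter in "ABCDEF":
    spec = dm.scenario_for_letter(letter)
    print(
        f"scenario {letter}: store {spec.storage.name.lower():<15} "
        f"send {spec.transmission.name.lower():<15} P = "
        f"{dm.scenario_privacy(spec):.3f}"
    )
# Reading the numbers: storing and sending nothing scores a perfect 1;
# sending only summaries halves it (0.5); any raw-data flow zeroes it.
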