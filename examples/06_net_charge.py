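"""Net-charge accounting for sequences and mutation sets.

Henderson-Hasselbalch fractional charges at a given pH; mutation deltas are
side-chain-only, so they equal the mutant-minus-original sequence charge.
"""

import hsgraft as hg

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
for pH in (5.0, 7.0, 9.0):
    print(f"pH {pH:4.1f}: net charge {hg.net_charge(seq, pH):+6.2f}")

up = hg.mutation_charge_delta(["S75K", "P176K"])
down = hg.mutation_charge_delta(["K42Q", "K43Q", "K243Q", "R244Q"])
print(f"\ncationizing set  S75K_P176K:            {up:+.2f}")
print(f"decationizing set K42Q_K43Q_K243Q_R244Q: {down:+.2f}")
print("each grafted lysine adds ~+1 e; each Lys/Arg→Gln removes ~1 e.")
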