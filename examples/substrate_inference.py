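"""Infer non-aqua substrates from specificity-determining positions.

Each member's nine SDP residues are compared against the per-substrate
allowed sets; mismatch positions are always reported, so lenient calls
(tolerance > 0) stay auditable.
"""

from aqpkit import classify
from aqpkit.io import load_sdp_tables

consensi, vectors = load_sdp_tables()

strict = classify.infer_substrates(vectors, consensi, tolerance=0)
urea = [c for c in strict if c.substrate == "urea" and c.classified
        and "NIP" in c.protein]
print(f"strict urea rule classifies {len(urea)} NIP members:")
for c in urea:
    print(f"  {c.protein}")

tip21 = next(c for c in strict
             if c.protein == "PruavTIP2;1" and c.substrate == "ammonia")
pos = ", ".join(f"SDP{i}" for i in tip21.mismatch_positions)
print(f"\nPruavTIP2;1 vs ammonia consensus: {tip21.mismatches} mismatches "
      f"({pos})")

lenient = classify.infer_substrates(vectors, consensi, tolerance={"co2": 1})
co2 = [c for c in lenient if c.substrate == "co2"]
print(f"\nCO2 rule at tolerance 1 classifies {sum(c.classified for c in co2)}"
      f" of {len(co2)} tabulated PIP vectors (all differ only at SDP3).")
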