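"""Composition ratios and absolute contents of the trial feeds and tissues.

Loads the built-in reference profiles (three experimental feeds and the
muscle they produced) and prints the dietary-quality ratios plus the
absolute muscle content of omega-3 long-chain PUFA.
"""

from famba import composition_ratios
from famba.deposition import tissue_absolute_content
from famba.reference import FEED_PROFILES, MUSCLE_PROFILES, OIL_PROFILES

print("Tuna oil DHA:EPA ratio:",
      composition_ratios(OIL_PROFILES["TO"], ndigits=1)["DHA:EPA"])

print("\nFeed ratios (n-3:n-6 and DHA:EPA describe how 'marine-like' a diet is):")
for diet, prof in FEED_PROFILES.items():
    r = composition_ratios(prof, ndigits=1)
    print(f"  {diet:>5}: n-3:n-6 = {r['n3:n6']}, DHA:EPA = {r['DHA:EPA']}")

print("\nMuscle n-3 LC-PUFA content, mg per 100 g dry matter")
print("(the fillet-quality figure a consumer ultimately receives):")
for diet in ("FO", "FOPO", "TOFX"):
    mg = tissue_absolute_content(MUSCLE_PROFILES[diet], "n-3 LC-PUFA")
    print(f"  {diet:>5}: {mg:6.0f}")
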