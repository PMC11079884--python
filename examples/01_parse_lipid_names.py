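"""Parse shorthand lipid names and classify them into lipid categories.

Identification software prints lipids as CLASS(chain/chain...), with
"d" marking a sphingoid base, "e"/"p" ether/plasmalogen linkages, and
"(rep)" a second measured ion of the same base lipid.
"""

from lipidiff import classify_category, parse_lipid_name, total_composition

names = [
    "DG(18:2/18:2)",
    "Cer(d18:2/24:1)",
    "PC(16:0p/16:0)",
    "TG(18:0e/18:1/18:1)",
    "LPC(16:0)(rep)",
]

for raw in names:
    name = parse_lipid_name(raw)
    carbons, bonds = total_composition(name)
    print(
        f"{raw:22s} class={name.class_code:6s} "
        f"category={classify_category(name.class_code).value:18s} "
        f"chains={len(name.chains)} C{carbons}:{bonds} "
        f"replicate={name.replicate}"
    )

# Each line shows the structured reading of one name: its class code and
# category, how many fatty chains it carries, the total carbon:double-bond
# composition, and whether it is a '(rep)' duplicate ion.
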