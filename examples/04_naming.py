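"""Validate aligned aliases against the cortical naming convention.

Aligned aliases name cortical types by conserved, cell-intrinsic
properties: layer + projection class for glutamatergic neurons, canonical
developmental marker genes for GABAergic interneurons, broad class for
non-neuronal cells, and historical names where they exist.
"""

from ccnkit.naming import AliasParseError, default_vocabulary, parse_aligned_alias, render_aligned_alias

vocab = default_vocabulary()
for text in ["L2/3 IT 4", "Pvalb 3", "Sst Chodl", "Microglia 2",
             "Chandelier 1", "L6 CT_1", "L5 CF 2", "Totally Free Text"]:
    try:
        term = parse_aligned_alias(text, vocab)
        print(f"{text!r:22} -> {term.cls:<14} canonical {render_aligned_alias(term)!r}")
    except AliasParseError as exc:
        print(f"{text!r:22} -> rejected: {exc}")
# 'L6 CT_1' normalizes to 'L6 CT 1'; 'L5 CF 2' maps the corticofugal alias
# CF onto the ET projection class; free text fails with the offending token.
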