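"""Dictionary and rule labelers on a hand-built sentence.

The dictionary labeler does longest-string matching against a term list
(case-insensitive, plural-normalized).  The rule labeler composes
phenotype candidates from quality modifiers plus head terms from
other-class lexicons: "high" + "IgE" + "levels" becomes one PH span.
"""

from phenorank import Lexicon, ModifierList, dict_label, rule_label

tokens = "Mice with high IgE levels and intestinal inflammation".split()

an_lexicon = Lexicon.build(["ileal mucosa", "lung"], "AN")
gg_lexicon = Lexicon.build(["IgE", "CD4"], "GG")
ds_lexicon = Lexicon.build(["inflammation", "asthma"], "DS")
modifiers = ModifierList.build(["high", "levels", "intestinal", "decreased"])

print("tokens:          ", tokens)
print("GG dictionary:   ", dict_label(tokens, gg_lexicon))
print("DS dictionary:   ", dict_label(tokens, ds_lexicon))
print(
    "rule labeler:    ",
    rule_label(tokens, modifiers, {"GG": gg_lexicon, "DS": ds_lexicon}),
)
# The rule labeler emits PH over "high IgE levels" (modifier + gene head +
# modifier) and over "intestinal inflammation" (modifier + disease head),
# while the plain dictionaries keep their own classes.
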