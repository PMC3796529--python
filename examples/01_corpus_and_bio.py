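"""Read a BRAT standoff document and inspect its BIO encoding.

Builds a two-sentence abstract with a phenotype mention that embeds a
gene mention, round-trips it through the BRAT reader/writer, and prints
the per-token BIO tags (the embedded gene is flattened to the outer
phenotype, which BIO cannot express).
"""

from phenorank import read_brat, write_brat

text = "Patients showed high IgE levels. The asthma phenotype persisted.\n"
ann = (
    "T1\tPH 16 31\thigh IgE levels\n"
    "T2\tGG 21 24\tIgE\n"
    "T3\tPH 37 53\tasthma phenotype\n"
)

doc = read_brat(text, ann, doc_id="example")
print(f"{doc.n_sentences} sentences, {len(doc.gold_mentions)} gold mentions")
for i in range(doc.n_sentences):
    for token, tag in zip(doc.token_texts(i), doc.gold_bio(i).tags):
        print(f"  {token:12s} {tag}")
    print()

round_trip = write_brat(doc)
print("BRAT round trip reproduces the annotation layer:")
print(round_trip)
# The nested GG survives in the mention layer (T2) even though the BIO
# encoding above shows only the outer PH span.
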