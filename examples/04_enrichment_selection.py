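"""Select candidate GO terms by EASE-score enrichment with FDR control.

The EASE score is a conservative Fisher variant: one gene is removed from
the list-term overlap before taking the hypergeometric upper tail, so terms
supported by a single gene can never look enriched.  Terms pass when
EASE < 0.05 and Benjamini-Hochberg FDR < 0.05 (both strict).
"""

from coexshift import enrich, select_terms

background = [f"GENE{k:03d}" for k in range(300)]
annotation = {
    "enriched_term": set(background[:40]),
    "flat_term_1": set(background[100:150]),
    "flat_term_2": set(background[200:240]),
}
# query hits 25 of the enriched term's 40 genes
query = background[:25] + background[280:]

results = enrich(query, annotation, background=background)
print(results.to_string(index=False,
                        formatters={"ease_p": "{:.3g}".format,
                                    "fdr_q": "{:.3g}".format}))
selected = select_terms(results, annotation)
print()
print(f"selected terms: {sorted(selected)}")
print("k of the n query genes fall in the term (K of N background genes);")
print("only terms with both a small EASE score and a small FDR q survive.")
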