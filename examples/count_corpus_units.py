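"""Count type frequencies under the four unit definitions.

Builds a miniature annotated corpus in memory (surface form, lemma, POS
tag) and shows how the vocabulary shrinks as words are aggregated into
lemmas — and how an ambiguous word ('found') is counted per token.
"""

from zipflemma import TokenRecord, Unit, build_lemma_map, count_frequencies, rank_frequency

records = [
    TokenRecord("houses", "house", "NNS"),
    TokenRecord("house", "house", "NN"),
    TokenRecord("housed", "house", "VBD"),
    TokenRecord("found", "find", "VBD"),
    TokenRecord("found", "found", "VBD"),
    TokenRecord("runs", "run", "VBZ"),
    TokenRecord("run", "run", "VB"),
]

for unit in Unit:
    t = count_frequencies(records, unit)
    print(f"{unit.value:>15}: V={t.V} L={t.L} <n>={t.mean_n:.2f}  {dict(sorted(t.counts.items()))}")

lmap = build_lemma_map(records)
print("\nword 'found' maps to lemmas:", sorted(lmap.word_to_lemmas["found"]))
print("lemmas with a single word form (ell_1):", lmap.ell1)
print("rank-frequency (word unit):", rank_frequency(count_frequencies(records, Unit.WORD)))
# L is identical in every unit (tokens are conserved); V shrinks under
# lemma aggregation; the word 'found' (n_w=2) exceeds each of its lemmas.
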