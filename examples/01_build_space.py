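"""Build a co-occurrence space and measure semantic neighborhood density.

Generates a small topic-structured corpus, builds a PPMI co-occurrence
space with the default HAL-style parameters (5/5 window, inverse-ramp
weighting, cosine similarity), derives the neighborhood membership
threshold from random word-pair similarities, and prints the density
measures for a few words: NCOUNT (how many words are unusually close),
INV-NCOUNT = 1/(NCOUNT+1), and ARC (how close the neighbors are on
average).  Words with many close neighbors live in dense contexts.
"""

import imgcalc as ic

docs, topic_of = ic.generate_corpus(ic.CorpusSpec(
    vocab_size=120, n_topics=4, n_documents=150, doc_length=60, seed=7))
space = ic.build_space(docs, ic.SpaceConfig(context_size=120, seed=7))
print(f"space: {len(space.vocabulary)} words x {space.matrix.shape[1]} "
      f"dimensions, {space.matrix.nnz} nonzero PPMI cells")

stats = ic.sample_pair_stats(space, n_pairs=20_000, seed=7)
theta = ic.neighbor_threshold(stats, lam=1.5)
print(f"random-pair cosine: mean={stats.mean:.3f} sd={stats.sd:.3f} "
      f"-> threshold = mean + 1.5 sd = {theta:.3f}")

table = ic.neighborhood_table(space, space.vocabulary[:5], threshold=theta)
print(table.to_string(index=False))
print("Each row: a word, the similarity threshold, how many words exceed "
      "it (ncount), 1/(ncount+1), and the mean similarity of those "
      "neighbors (arc).")
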