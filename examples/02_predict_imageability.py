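"""Apply the published imageability models to new feature rows.

The full model predicts a word's 1-7 imageability judgment from its
cosine similarity to seven emotion seed terms, its neighborhood density
(ARC, INV-NCOUNT), its length, and its log corpus frequency.  Here two
hypothetical words illustrate the model's logic: a "concrete-profile"
word (close to pleasure/horny/proud, dense neighborhood, frequent) and
an "abstract-profile" word (close to admirable/arouse/good, sparse
neighborhood).  The CONTEXT and EMOTIONALITY composites are the
density and emotion-term parts of the same weighted sum.
"""

import pandas as pd

import imgcalc as ic

full = ic.load_pretrained("full")
rows = pd.DataFrame({
    # emotion-term cosine similarities
    "admirable": [0.02, 0.12], "arouse": [0.03, 0.10],
    "envious": [0.01, 0.05], "good": [0.05, 0.15],
    "horny": [0.06, 0.01], "pleasure": [0.12, 0.04], "proud": [0.08, 0.03],
    # density + lexical covariates
    "arc": [0.55, 0.35], "inv_ncount": [0.02, 0.50],
    "length": [5.0, 8.0], "lnfrequency": [8.0, 4.0],
}, index=["concrete_profile", "abstract_profile"])

pred = ic.apply_pretrained(rows, full)
comp = ic.composite_scores(rows, full)
out = pd.concat([pred, comp[["context_score", "emotionality_score"]]],
                axis=1)
print(out.round(3).to_string())
print("predicted_imageability is on the 1-7 judgment scale (unclamped); "
      "higher context/emotionality composites both push it upward.")
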