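"""EMT and metabolism scores on a set of log2 expression changes.

The score is (sum of up-gene log2 fold changes − sum of down-gene log2
fold changes) / number of genes used. A positive EMT score means the
sample moved towards a mesenchymal state; a positive metabolism score
means oxidative phosphorylation rose relative to glycolysis.
"""

from emtconv.scoring import (
    ExpressionChanges,
    emt_score_qpcr,
    load_emt_signature,
    load_metabolism_sets,
    metabolism_score,
    signature_score,
)

# a mid-conversion sample: mesenchymal genes up, epithelial genes down
changes = ExpressionChanges(
    {
        "Cdh2": 1.8, "Fn1": 1.2, "Snai2": 0.9, "Zeb1": 0.6,   # up in EMT
        "Epcam": -1.1, "Ocln": -0.8,                          # down in EMT
        "Vim": 1.5, "Cdh1": -1.3, "Krt18": -0.7,
        "Ndufa1": 0.4, "Cox5a": 0.3, "Gapdh": -0.5, "Pkm": -0.2,
    },
    sample="day6",
    provenance="qPCR",
    species="mouse",
)

q = emt_score_qpcr(changes)
print(f"qPCR EMT score        {q.score:+.3f}  (n_used={q.n_used})")

sig = load_emt_signature()          # shipped synthetic stand-in signature
r = signature_score(changes, sig)
print(f"signature EMT score   {r.score:+.3f}  (n_used={r.n_used})")

ox, gly = load_metabolism_sets()    # KEGG00190 vs KEGG00010 members
m = metabolism_score(changes, ox, gly)
print(f"metabolism score      {m.score:+.3f}  (n_used={m.n_used})")

# Positive EMT scores: this sample is in the mesenchymal (early) phase.
# The positive metabolism score says oxidative phosphorylation genes
# rose while glycolysis genes fell. Snai2 was accepted as Slug via the
# alias table; absent signature genes were simply excluded from both
# numerator and denominator (see n_used).
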