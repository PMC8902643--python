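"""Score circRNA-disease pairs with the full two-stage pipeline.

fit_pipeline trains both embedding networks and the pseudo-siamese classifier
on all labeled pairs (observed associations as positives, an equal number of
sampled non-associations as negatives), then any pair can be scored.
"""

from circlink import fit_pipeline
from circlink.psn import predict_pairs
from circlink.synthetic import PlantedBlockConfig, generate_planted

data = generate_planted(PlantedBlockConfig(seed=0))
pipeline = fit_pipeline(data.tables, seed=0)

# one disease from the same planted group as circ_0001, one from a different group
circ = "circ_0001"
diseases = [f"dis_{j:04d}" for j in range(1, 21)]
same_dis = next(d for d in diseases if data.groups[d] == data.groups[circ])
cross_dis = next(d for d in diseases if data.groups[d] != data.groups[circ])
pairs = [(circ, same_dis), (circ, cross_dis), ("circ_0002", cross_dis)]
probs = predict_pairs(
    pipeline.psn_model, pipeline.disease_embeddings, pipeline.circ_embeddings, pairs
)
for (c, d), p in zip(pairs, probs):
    same = data.groups[c] == data.groups[d]
    print(f"P({c} ~ {d}) = {p:.3f}   [{'same' if same else 'different'} planted group]")
print("\nprobabilities near 1 indicate a predicted association; same-group pairs should score high")
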