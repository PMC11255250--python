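"""Residue featurization: one-hot + physicochemical + skip-gram embedding.

Trains per-residue skip-gram embeddings on a tiny synthetic corpus and
shows the feature layout of one record.
"""

from tcnss import synthetic
from tcnss.featurize import PhysChemTable, featurize_record, train_embeddings
from tcnss.seqdata import Q3

records = synthetic.generate(synthetic.GeneratorConfig(
    n_records=20, length_range=(30, 50), seed=0))
emb = train_embeddings([r.sequence for r in records], k=1, dim=16,
                       epochs=5, seed=0)
table = PhysChemTable.default()

rec = records[0]
fm = featurize_record(rec, table, emb)
print(f"record {rec.id}: {rec.length} residues, labels {rec.labels(Q3)[:20]}...")
print(f"feature matrix: {fm.rows.shape[0]} rows x {fm.rows.shape[1]} columns "
      "(21 one-hot + 7 physicochemical + 16 embedding)")
print("row 0 one-hot block:", fm.rows[0, :21].astype(int))
print("row 0 physchem block (polarity one-hot, charge, size, hydropathy):",
      fm.rows[0, 21:28].round(3))
print("helix-former similarity  A~L:", round(emb.similarity("A", "L"), 3))
print("cross-class similarity   A~G:", round(emb.similarity("A", "G"), 3))
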