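"""Twin-network training: regress cosine similarity onto TM-score bins.

Trains the mini aggregator preset for a few epochs on a small synthetic
benchmark and prints the loss trajectory, the validation AUPRC used for
checkpoint selection, and the Spearman correlation between cosine
similarity and oracle TM on the held-out pairs.
"""

import numpy as np
from scipy.stats import spearmanr

from foldvec.model import AggregatorConfig, EncoderConfig, aggregate_tensor, encode_residues
from foldvec.nn import Tensor
from foldvec.synthetic import generate_benchmark
from foldvec.tmscore import pairwise_tm_table
from foldvec.training import TrainingConfig, train

bench = generate_benchmark(3, 2, 2, 2, master_seed=0, length_range=(60, 90))
pairs = pairwise_tm_table(bench.structures)

enc = EncoderConfig()
agg = AggregatorConfig.mini_preset()
cfg = TrainingConfig(epochs=8, warmup_epochs=2, pairs_per_epoch=768,
                     batch_size=48, validation_fraction=0.05, master_seed=0)
weights, history = train(bench, enc, agg, cfg, pairs=pairs)

for e, (loss, auprc) in enumerate(zip(history.train_loss, history.val_auprc)):
    print(f"epoch {e:2d}  loss {loss:.4f}  val AUPRC {auprc:.3f}")
print(f"best epoch: {history.best_epoch}")

emb = {s.source: aggregate_tensor(Tensor(encode_residues(s, enc).embeddings),
                                  agg, weights).data
       for s in bench.structures}
cos = [float(emb[p.id1] @ emb[p.id2]
             / (np.linalg.norm(emb[p.id1]) * np.linalg.norm(emb[p.id2])))
       for p in history.val_pairs]
rho = spearmanr(cos, [p.tm_max for p in history.val_pairs]).statistic
print(f"\nheld-out Spearman(cosine, oracle TM) = {rho:.3f}")
print("Cosine similarity of the trained embeddings tracks the TM-score: "
      "that ordering is what makes embedding retrieval rank true structural "
      "neighbours first.")
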