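"""Cold-start prediction of signed interactions for new drugs.

A new drug has no known interactions, so its network row is empty.  We
bridge the gap with binary feature profiles: train BRSNMF plus a
partial-least-squares map from features to the latent indicators on known
drugs, then score a held-out drug's interactions from its features alone.
"""

import numpy as np

from ddibalance import (
    BrsnmfConfig,
    coldstart_benchmark,
    evaluate_ranking,
    predict,
    train,
)
from ddibalance.factorization import default_prediction_rank

net, part, features = coldstart_benchmark(seed=0)
print(f"benchmark: {net.n_nodes} drugs, {net.n_edges} interactions, "
      f"{features.n_features} binary features")

# hold out the last 10 drugs as "new" drugs
held_out = np.arange(net.n_nodes - 10, net.n_nodes)
kept = np.arange(net.n_nodes - 10)
sub_net = net.subnetwork(kept)
k = default_prediction_rank(sub_net)
print(f"latent dimension k = {k} (rank/10 default)")

model = train(sub_net, features.subset(kept), BrsnmfConfig(k=k, seed=0))
pred = predict(model, features.subset(held_out))

truth = net.adjacency[np.ix_(held_out, kept)]
metrics = evaluate_ranking(truth, pred, n_list=(10,))
print(f"\nheld-out evaluation over {metrics.n_pairs} pairs "
      f"({metrics.n_enhancive} enhancive, {metrics.n_degressive} degressive):")
print(f"  AUROC = {metrics.auroc:.3f}")
print(f"  AUPR  = {metrics.aupr:.3f}")
print(f"  MPR   = {metrics.mpr:.3f}  (0 = every true interaction ranked first)")
print(f"  top-10 enhancive accuracy = {metrics.top_n_accuracy[10]:.2f}")

print("\nstrongest predicted interactions:")
for q, t, s in pred.ranked_pairs()[:5]:
    print(f"  {q} -- {t}: score {s:+.3f}")
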