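"""Online model update with review training on a two-domain benchmark.

Domain B re-observes half of the catalog under a strongly shifted presence
regime. Updating on it without replaying old cells makes the model forget
the types absent from the new data; review training (replaying a random
sample of the retained previous training pool after each epoch) prevents
the forgetting.
"""

import warnings

import cellpresence as cp

cfg = cp.SyntheticConfig(n_types=6, markers_per_type=20,
                         n_background_genes=400, cells_per_type=250, seed=11)
bench = cp.generate_domain_shift_benchmark(cfg, seed=11)
print(f"domain B covers only: {', '.join(bench.types_in_b)}")


def old_domain_accuracy(review_size):
    model = cp.init_model(cp.NetworkConfig(input_size=bench.gene_space.size),
                          bench.catalog, bench.gene_space, seed=11)
    cw = cp.compute_class_weights(bench.train_a[1], bench.catalog)
    model, _ = cp.train(model, *bench.train_a,
                        cp.TrainConfig(seed=11, max_epochs=15, batch_size=256), cw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model, _ = cp.online_update(
            model, *bench.train_b,
            cp.TrainConfig(seed=11, max_epochs=30, patience=30, batch_size=256),
            cp.ReviewPolicy(review_size=review_size, seed=11),
            replay_pool=bench.train_a,
        )
    pred, _ = cp.predict(model, bench.test_a[0])
    return cp.concordance(pred, bench.test_a[1])


with_review = old_domain_accuracy(1000)
without_review = old_domain_accuracy(0)
print(f"old-domain accuracy with review training:    {with_review:.3f}")
print(f"old-domain accuracy without review training: {without_review:.3f}")
print("The gap is catastrophic forgetting; replaying previous training "
      "cells after each epoch closes it.")
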