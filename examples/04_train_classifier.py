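"""Train the VGG-style CNN on a small single-domain dataset.

Uses the desk-scale widths (same 7-conv / 3-pool / 4-FC census as the full
architecture) and prints the per-epoch learning curves.
"""

from pcgmel import (DatasetSpec, TrainConfig, build_model,
                    extract_segment_dataset, generate_dataset,
                    make_domain_channels, train)
from pcgmel.model import small_architecture

spec = DatasetSpec(domains={"a": (20, 12)}, seed=0, record_seconds=3.0)
channels = make_domain_channels(1, seed=0)
records, _ = generate_dataset(spec, channels)
ds = extract_segment_dataset(records, "log_mel")
print(f"{ds.X.shape[0]} segments of shape {ds.X.shape[1:]}")

net = build_model(small_architecture(), seed=0)
result = train(net, ds.X, ds.labels, ds.record_ids,
               TrainConfig(learning_rate=1e-3, batch_size=16, epochs=8,
                           seed=0))
for i, row in result.to_dataframe().iterrows():
    print(f"epoch {int(row.epoch):2d}: train acc {row.train_acc:.3f} "
          f"loss {row.train_loss:.3f} | val acc {row.val_acc:.3f}")
print(f"best validation accuracy: {result.best_val_acc:.3f} "
      f"(epoch {result.best_epoch + 1})")
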