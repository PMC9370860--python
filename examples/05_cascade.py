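"""The full three-stage pseudo-labeling cascade on synthetic scenes.

Trains First CE (auto-labeled neutral scenes), Final CE (+ pseudo-labeled
harsh-light scenes), TNA (+ zero-mask true negatives) and FIA (+ raw
pseudo-labeled field frames), then scores all four on a shared field-style
test set with dry-leaf confusers. Expect the trade the cascade is built
around: TNA raises precision and lowers recall relative to CE; FIA keeps
recall while balancing precision, giving the best F1.

Takes a few minutes on one CPU core.
"""

from fruitseg import CascadeConfig, TrainHyperparams, run_cascade

config = CascadeConfig(seed=0, hyperparams=TrainHyperparams(epochs=8, seed=0))
result = run_cascade(config)

for log in result.logs:
    print(
        f"{log['stage']:16s} {log['pre_augmentation_count']:3d} originals "
        f"-> {log['post_augmentation_count']:4d} after 20x augmentation, "
        f"final loss {log['final_loss']:.4f}"
    )

print()
for tag in ("first_ce", "ce", "tna", "fia"):
    pct = result.reports[tag].as_percentages()
    print(
        f"{tag:9s} P={pct['precision']:6.2f}%  R={pct['recall']:6.2f}%  "
        f"F1={pct['f1']:6.2f}%"
    )
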