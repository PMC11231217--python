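"""FLOP and parameter-memory accounting.

Reproduces the block-level FLOP totals at the reference dimensions
(K=8, Cin=Cout=64, 128x128 output, one convolution = 2^30 FLOPs), then
prices the actual assembled architecture and estimates its parameter
memory at 4 bytes per parameter.
"""

from icnet import ModelConfig, block_flops, build_model, count_parameters, memory_estimate, model_flop_table

print("block totals at reference dimensions:")
for kind in ("MA", "Attention", "FCN"):
    print(f"  {kind:<10} {block_flops(kind):>14,} FLOPs")
total = sum(block_flops(k) for k in ("MA", "Attention", "FCN"))
print(f"  {'sum':<10} {total:>14,} FLOPs")

config = ModelConfig(input_height=128, input_width=128)
table = model_flop_table(config)
print(f"\nassembled 128x128 full-width network: {len(table)} convolutions, "
      f"{sum(r.flops for r in table):,} FLOPs per forward pass")

counts = count_parameters(build_model(config))
mb = memory_estimate(counts["trainable"], counts["non_trainable"], bytes_per_param=4)
print(f"parameters: {counts['trainable']:,} trainable + "
      f"{counts['non_trainable']:,} non-trainable "
      f"-> {mb:.2f} MB at 4 bytes/parameter")
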