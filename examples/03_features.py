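"""Extract the hierarchical feature table for one section.

Each training sample is one randomly chosen pixel per superpixel; its
vector concatenates the 34 pixel-level filter responses, 35 superpixel
statistics (34 channel means + intensity entropy) and 3 context statistics
of the neighboring superpixels — 72 dimensions in total.
"""

from hlfseg.config import PipelineConfig
from hlfseg.features_hlf import FEATURE_NAMES, assemble_hlf, select_samples
from hlfseg.pipeline import process_image
from hlfseg.synthetic_data import SyntheticSpec, generate_synthetic_em

image, mask = generate_synthetic_em(SyntheticSpec(seed=42))
config = PipelineConfig(seed=42)
feats = process_image(image, config)
samples = select_samples(feats.superpixels, mask, seed=42)
table = assemble_hlf(
    feats.stack, feats.superpixels, feats.spx_feats, feats.ctx, samples, gt=mask
)

print(f"pixel feature channels: {feats.stack.shape[0]}")
print(f"superpixel block width: {feats.spx_feats.shape[1]}")
print(f"context block width:    {feats.ctx.shape[1]}")
print(f"samples x features:     {len(table)} x {len(FEATURE_NAMES)}")
print(f"membrane samples:       {table['label'].mean():.3f} of the table")
print("first features:        ", ", ".join(FEATURE_NAMES[:4]), "...")
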