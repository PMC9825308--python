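"""Compose imbalance-aware minibatches for one training epoch.

Every minibatch holds 17 original samples plus 15 synthetic entries; 65%
of iterations supplement with minority-class triples (GCT + NL mixup (R)
+ NL mixup (G)) and 35% with medium-class GCT variants.
"""

from collections import Counter

from nlmixup import (
    ImbalanceAwareSampler,
    SamplerConfig,
    build_profile,
    generate_label_matrix,
    make_imbalanced_preset,
)

matrix = generate_label_matrix(make_imbalanced_preset("tiny"))
profile = build_profile(matrix)
config = SamplerConfig(iterations_per_epoch=20, seed=5)
sampler = ImbalanceAwareSampler(matrix, profile, config)

manifests = list(sampler.epoch(0))
kinds = Counter(m.kind for m in manifests)
print(f"{len(manifests)} iterations: {kinds['minority']} minority, {kinds['medium']} medium")

first = manifests[0]
print(f"iteration 0 ({first.kind}): {len(first.original_ids)} originals + "
      f"{len(first.supplementary)} synthetic = {first.size}")
ops = Counter(r.operator for r in first.supplementary)
print("synthetic operators:", dict(ops))
print("classes supplemented:", sorted({r.class_id for r in first.supplementary}, key=int))

# Manifests carry provenance only (parent ids, operator, theta); pixels are
# materialized lazily via nlmixup.materialize_record inside a training loop.
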