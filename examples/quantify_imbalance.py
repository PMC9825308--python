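"""Quantify multilabel imbalance on a synthetic right-skewed dataset.

Builds the 297-instance "tiny" preset label table (no pixels needed),
computes the imbalance ratio per label (IRL), partitions the classes, and
evaluates the SCUMBLE concurrence score that decides whether minority
oversampling is expected to help.
"""

from nlmixup import build_profile, compute_scumble, generate_label_matrix, make_imbalanced_preset

matrix = generate_label_matrix(make_imbalanced_preset("tiny"))
profile = build_profile(matrix)
report = compute_scumble(matrix)

print(f"{matrix.n_instances} instances x {matrix.n_labels} labels")
print("IRL per label:", {k: round(v, 2) for k, v in profile.irl.items()})
print(f"IRL mean {profile.irl_mean:.2f}, median {profile.irl_median:.2f}")
print("minority classes (IRL > mean):      ", profile.minority)
print("medium classes (median < IRL < mean):", profile.medium)
print(f"dataset SCUMBLE = {report.dataset_value:.4f}")
print("oversampling expected to help:", report.benefits_from_resampling)

# The most frequent label always has IRL 1; labels rarer by a factor f have
# IRL f.  A SCUMBLE well below 0.1 means majority and minority labels rarely
# share an image, so synthetic minority samples will not drag majority
# labels along with them.
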