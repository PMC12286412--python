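"""Bias-variance decomposition and the PR-AUC floor.

Decomposes a classifier's 0-1 test loss into bias and variance over
bootstrap resamples of the training set, and shows the precision-recall
baseline every PR-AUC must be judged against.
"""

from fwf.datasets import DatasetVariantSpec
from fwf.evaluate import ModelSpec, bias_variance_decompose, pr_baseline, temporal_split
from fwf.experiment import _prepare_variant
from fwf.features import WindowSet
from fwf.model import PlayerRoster
from fwf.simulate import generate_season, preset

records, calendar, report, _ = generate_season(preset("smoke_test", seed=2))
roster = PlayerRoster(sorted(records["player_id"].unique().tolist()))
table = _prepare_variant(records, calendar, roster, report,
                         DatasetVariantSpec("fwf", taus=WindowSet((1, 2, 3))))
train, test = temporal_split(table)

loss, bias, var = bias_variance_decompose(
    ModelSpec("CART"), train.X, train.y, test.X, test.y, n_bootstrap=100, seed=0
)
print(f"expected 0-1 loss : {loss:.4f}")
print(f"bias              : {bias:.4f}")
print(f"variance          : {var:.4f}")
print(f"PR-AUC baseline of the test rows: {pr_baseline(test.y):.4f}"
      if test.y.sum() else "test tail has no positives for a PR baseline")

# Bias is the error of the bootstrap-majority prediction (systematic
# error); variance is how often individual refits disagree with that
# majority (instability).  A tree on a tiny table is typically
# low-bias / high-variance; the PR baseline equals test prevalence.
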