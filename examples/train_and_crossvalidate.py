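"""Train the mixture-of-experts classifier on a synthetic benchmark and
cross-validate it with leakage-free SMILES folds.

Generates ~300 peptide-like molecules with a known latent permeability
function, swing-labels the PAMPA records, assigns 3 folds by unique SMILES,
and reports accuracy / MCC / AUC / BCE per fold.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore")

from macroperm.chemdata import Label
from macroperm.evalx import cross_validate
from macroperm.macro_pp import MacroPPConfig, _BundleCache, fit_classifier
from macroperm.nets import MPConfig
from macroperm.splits import assign_folds
from macroperm.synthetic import SyntheticSpec, make_benchmark

spec = SyntheticSpec(n_large=220, n_task=80, seed=5)
large, _, _ = make_benchmark(spec)
records = [lr for lr in large if lr.label is not Label.EXCLUDED]
print(f"{len(records)} labeled records "
      f"({np.mean([int(r.label) for r in records]):.0%} permeable)")

folds = assign_folds([lr.record for lr in records], mode="SMILES", k=3, seed=5).folds
cache = _BundleCache()
cfg = MacroPPConfig(mp=MPConfig(rounds=2, hidden_dim=16), max_epochs=8, patience=8)


def builder(train_records, seed):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_records))
    n_val = max(1, len(train_records) // 5)
    val = [train_records[i] for i in order[:n_val]]
    train = [train_records[i] for i in order[n_val:]]
    model, _ = fit_classifier(train, val, cfg, seed=seed, cache=cache)
    return model


report = cross_validate(builder, records, folds, seed=0)
for metric, stats in report.summary().items():
    print(f"  {metric}: {stats['mean']:.3f} +/- {stats['sd']:.3f}")
print(
    "Interpretation: AUC well above 0.5 means the model recovers the planted"
    " permeability signal; fold variation reflects the small per-fold sample."
)
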