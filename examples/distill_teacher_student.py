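"""Knowledge distillation: a multi-assay teacher transfers soft labels to a
small task-specific student.

Trains a teacher on a pooled Caco-2/MDCK/RRCK set, then trains two students
on a small PAMPA task set - one plain, one with temperature-scaled soft
labels (T = 2, lambda = 0.5) - and compares validation AUC.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore")

from macroperm.chemdata import Label
from macroperm.distill import DistillConfig, distill_student, train_teacher
from macroperm.evalx import ranking_metrics
from macroperm.macro_pp import MacroPPConfig, _BundleCache, fit_classifier
from macroperm.nets import MPConfig
from macroperm.synthetic import SyntheticSpec, make_benchmark

spec = SyntheticSpec(n_large=400, n_task=120, seed=9)
large, task, _ = make_benchmark(spec)
kept_large = [l for l in large if l.label is not Label.EXCLUDED]
kept_task = [l for l in task if l.label is not Label.EXCLUDED]
cache = _BundleCache()

rng = np.random.default_rng(0)
order = rng.permutation(len(kept_large))
val_l = [kept_large[i] for i in order[:120]]
train_l = [kept_large[i] for i in order[120:]]
tcfg = MacroPPConfig(mp=MPConfig(rounds=2, hidden_dim=16), max_epochs=6,
                     patience=6, batch_size=64)
teacher, _ = train_teacher(train_l, val_l, tcfg, seed=0, cache=cache)
t_auc = ranking_metrics([int(l.label) for l in val_l],
                        teacher.predict_proba(val_l))["auc"]
print(f"teacher: {len(train_l)} multi-assay records, val AUC {t_auc:.3f}")

o = rng.permutation(len(kept_task))
val_t = [kept_task[i] for i in o[:30]]
train_t = [kept_task[i] for i in o[30:]]
scfg = MacroPPConfig(mp=MPConfig(rounds=2, hidden_dim=16), max_epochs=15,
                     patience=8)
y = [int(l.label) for l in val_t]

plain, _ = fit_classifier(train_t, val_t, scfg, seed=1, cache=cache)
student, _, targets = distill_student(
    teacher, train_t, val_t, DistillConfig(temperature=2.0, lam=0.5),
    scfg, seed=1, cache=cache,
)
auc_plain = ranking_metrics(y, plain.predict_proba(val_t))["auc"]
auc_dist = ranking_metrics(y, student.predict_proba(val_t))["auc"]
print(f"plain student AUC     {auc_plain:.3f}")
print(f"distilled student AUC {auc_dist:.3f}")
print(f"teacher soft labels span [{targets.probabilities.min():.2f}, "
      f"{targets.probabilities.max():.2f}] at T = {targets.temperature}")
print(
    "Interpretation: the distilled student absorbs the teacher's smoothed view"
    " of the shared latent function. On a single small swing-cleaned task set"
    " both students sit near ceiling; the benefit is a statistical statement"
    " (median over paired seeds), asserted in the acceptance suite."
)
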