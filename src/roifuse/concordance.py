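"""Agreement and diversity between classifiers.

Two indices quantify how similarly two classifiers (e.g. ones trained on
different modalities) behave on the same subjects:

* the Jaccard coefficient |A ∩ B| / |A ∪ B| between the two sets of
  correctly classified subjects, and
* Cohen's kappa (Pr(a) - Pr(e)) / (1 - Pr(e)) between the two predicted
  label vectors, treating the classifiers as raters.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 1.0 when both sets are empty."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        return 1.0
    return len(set_a & set_b) / len(union)


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two equal-length label vectors.

    Pr(a) is the observed agreement fraction; Pr(e) the expected chance
    agreement from the two raters' marginal label frequencies.  When both
    raters are constant with identical marginals (Pr(e) = 1), perfect
    agreement returns 1.0 and anything else is an error.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need two equal-length, nonempty label vectors")
    pr_a = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pr_e = float(pa @ pb)
    if pr_e >= 1.0:
        if pr_a == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but raters disagree")
    return (pr_a - pr_e) / (1.0 - pr_e)


def consensus_predictions(
    oof_predictions: np.ndarray, positive_label, negative_label
) -> np.ndarray:
    """Majority out-of-fold vote over repeats; ties go to the positive class."""
    votes = (np.asarray(oof_predictions) == positive_label).mean(axis=0)
    if np.any(votes == 0.5):
        warnings.warn("majority-vote tie(s) resolved to the positive class", stacklevel=2)
    return np.where(votes >= 0.5, positive_label, negative_label)


def prediction_table(
    true_labels: np.ndarray,
    predictions: dict[str, np.ndarray],
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-subject table of true and per-classifier predicted labels."""
    true_labels = np.asarray(true_labels)
    n = true_labels.size
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame({"subject": subject_ids, "true": true_labels})
    for name, pred in predictions.items():
        pred = np.asarray(pred)
        if pred.shape != true_labels.shape:
            raise ValueError(f"predictions for {name!r} have wrong length")
        df[name] = pred
    return df


def pairwise_concordance(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    jaccard_on: str = "correct",
) -> pd.DataFrame:
    """Jaccard and kappa for each classifier pair in a prediction table.

    By default Jaccard is computed on the sets of correctly classified
    subjects; ``jaccard_on="positive"`` uses the predicted-positive sets
    instead.  Kappa always compares the two predicted-label vectors.
    """
    classifiers = [c for c in table.columns if c not in ("subject", "true")]
    for name in classifiers:
        if table[name].nunique() > 2:
            raise ValueError(f"classifier {name!r} has more than two predicted labels")
    if pairs is None:
        pairs = list(combinations(classifiers, 2))
    truth = table["true"].to_numpy()
    positive = truth.max()
    rows = []
    for a, b in pairs:
        for name in (a, b):
            if name not in classifiers:
                raise ValueError(
                    f"unknown classifier {name!r}; available: {classifiers}"
                )
        pa, pb = table[a].to_numpy(), table[b].to_numpy()
        if jaccard_on == "correct":
            sa = set(table["subject"][pa == truth])
            sb = set(table["subject"][pb == truth])
        elif jaccard_on == "positive":
            sa = set(table["subject"][pa == positive])
            sb = set(table["subject"][pb == positive])
        else:
            raise ValueError("jaccard_on must be 'correct' or 'positive'")
        rows.append(
            {
                "classifier_a": a,
                "classifier_b": b,
                "jaccard": jaccard(sa, sb),
                "kappa": cohen_kappa(pa, pb),
            }
        )
    return pd.DataFrame(rows)
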