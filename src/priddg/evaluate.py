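"""Evaluation protocols: regression/classification metrics, three
cross-validation schemes, and dataset curation.

CV1 repeats a random 50/50 mutation split, CV2 a random 80/20 split (100
rounds each by default, aggregate = mean per-round R and RMSE); CV3 is
leave-one-complex-out: each fold holds out one complex with all its
mutations, and the aggregate metrics are computed on the pooled
out-of-fold predictions. The classification view labels mutations with
experimental ddG >= 1 kcal/mol as highly decreasing and reports AUC-ROC,
AUC-PR and the maximal MCC over prediction thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import FEATURE_NAMES, fit as fit_model, predict as model_predict

__all__ = ["EvaluationReport", "regression_metrics", "classification_metrics",
           "max_mcc", "cross_validate", "curate_dataset",
           "HIGHLY_DECREASING_THRESHOLD"]

HIGHLY_DECREASING_THRESHOLD = 1.0  # kcal/mol


@dataclass
class EvaluationReport:
    r: float
    rmse: float
    slope: float
    auc_roc: float | None = None
    auc_pr: float | None = None
    max_mcc: float | None = None
    n: int = 0

    def as_dict(self):
        return asdict(self)


def regression_metrics(pred, exp):
    """(Pearson R, RMSE, slope) between predicted and experimental ddG.

    RMSE = sqrt(mean squared residual); slope is from the least-squares
    line of experimental on predicted values.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValueError("pred and exp must be equal-length 1-D vectors")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.std(pred) == 0 or np.std(exp) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(pred, exp)[0, 1])
    rmse = float(np.sqrt(np.mean((pred - exp) ** 2)))
    slope = float(np.polyfit(pred, exp, 1)[0])
    return r, rmse, slope


def max_mcc(pred, labels):
    """Maximal Matthews correlation coefficient over all distinct prediction
    thresholds (predicted positive = pred >= t); any zero denominator factor
    gives MCC = 0 at that threshold."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = -1.0
    for t in np.unique(pred):
        pp = pred >= t
        tp = float(np.sum(pp & labels))
        tn = float(np.sum(~pp & ~labels))
        fp = float(np.sum(pp & ~labels))
        fn = float(np.sum(~pp & labels))
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        best = max(best, mcc)
    return best


def classification_metrics(pred, exp, threshold=HIGHLY_DECREASING_THRESHOLD):
    """(AUC-ROC, AUC-PR, max-MCC) for separating highly decreasing
    mutations (experimental ddG >= ``threshold``) by predicted ddG."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    labels = exp >= threshold
    if labels.all() or not labels.any():
        raise ValueError("both classes required for classification metrics")
    auc_roc = float(roc_auc_score(labels, pred))
    auc_pr = float(average_precision_score(labels, pred))
    return auc_roc, auc_pr, float(max_mcc(pred, labels))


def _fit_predict(train, test):
    model = fit_model(train)
    return model_predict(model, test)


def cross_validate(dataset, scheme="CV3", repeats=100, seed=0):
    """Cross-validate the linear model on a featurized dataset.

    ``dataset``: DataFrame with the 11 feature columns, ``ddg_exp`` and
    ``pdb_id`` (complex identifier, needed for CV3). Returns a dict with
    ``per_round`` (list of EvaluationReport) and ``aggregate``.
    Deterministic for a fixed seed.
    """
    df = dataset.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(df)

    if scheme in ("CV1", "CV2"):
        frac_train = 0.5 if scheme == "CV1" else 0.8
        rounds = []
        for _ in range(repeats):
            perm = rng.permutation(n)
            n_train = int(round(frac_train * n))
            tr, te = perm[:n_train], perm[n_train:]
            pred = _fit_predict(df.iloc[tr], df.iloc[te])
            r, rmse, slope = regression_metrics(pred, df.iloc[te]["ddg_exp"])
            rounds.append(EvaluationReport(r, rmse, slope, n=len(te)))
        aggregate = EvaluationReport(
            r=float(np.mean([x.r for x in rounds])),
            rmse=float(np.mean([x.rmse for x in rounds])),
            slope=float(np.mean([x.slope for x in rounds])),
            n=n,
        )
        return {"scheme": scheme, "per_round": rounds, "aggregate": aggregate}

    if scheme != "CV3":
        raise ValueError(f"unknown scheme {scheme!r}")

    complexes = list(dict.fromkeys(df["pdb_id"]))
    if len(complexes) < 2:
        raise ValueError("CV3 needs at least two complexes")
    pooled_pred = np.full(n, np.nan)
    rounds = []
    for cid in complexes:
        te_mask = (df["pdb_id"] == cid).to_numpy()
        tr_df, te_df = df[~te_mask], df[te_mask]
        if len(tr_df) <= len(FEATURE_NAMES) + 1:
            raise ValueError(
                f"degenerate CV3 fold: complex {cid} leaves too few "
                "training mutations")
        pred = _fit_predict(tr_df, te_df)
        pooled_pred[te_mask] = pred
        rounds.append({"complex": cid, "n_test": int(te_mask.sum())})
    exp = df["ddg_exp"].to_numpy(dtype=float)
    r, rmse, slope = regression_metrics(pooled_pred, exp)
    labels = exp >= HIGHLY_DECREASING_THRESHOLD
    if labels.any() and not labels.all():
        auc_roc, auc_pr, mcc = classification_metrics(pooled_pred, exp)
    else:
        auc_roc = auc_pr = mcc = None
    aggregate = EvaluationReport(r, rmse, slope, auc_roc, auc_pr, mcc, n=n)
    return {
        "scheme": "CV3", "per_round": rounds, "aggregate": aggregate,
        "pooled_predictions": pooled_pred,
    }


def category_report(dataset, predictions, column, value):
    """Metrics restricted to rows where ``column == value`` (reporting
    filter over pooled predictions, e.g. alanine-scanning vs not)."""
    mask = (dataset[column] == value).to_numpy()
    pred = np.asarray(predictions)[mask]
    exp = dataset["ddg_exp"].to_numpy(dtype=float)[mask]
    r, rmse, slope = regression_metrics(pred, exp)
    return EvaluationReport(r, rmse, slope, n=int(mask.sum()))


def rna_identity(seq_a, seq_b):
    """Global-alignment identity between two RNA sequences: matched
    positions of the best global alignment over the longer length."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a.upper().replace("T", "U"),
                        seq_b.upper().replace("T", "U"))[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / max(len(seq_a), len(seq_b))


REQUIRED_COLUMNS = ["pdb_id", "protein_chain", "position", "wt_aa", "mut_aa",
                    "ddg_exp"]


def curate_dataset(raw, similarity_threshold=0.8):
    """Apply the training-set curation filters to a raw mutation table.

    In order: per-row validity; modified residues at the binding interface
    (``interface_modified`` flag); protein shorter than 20 residues or RNA
    shorter than 5 nucleotides; mutations at metal coordination sites
    (``metal_site`` flag); RNA sequence identity between structure and
    assay below 80% (only when both ``rna_seq_structure`` and
    ``rna_seq_assay`` are given); multiple measurements of one mutation are
    averaged when their spread is < 1 kcal/mol and rejected otherwise.

    Returns ``(curated DataFrame, rejection report)`` where the report is a
    list of ``(row index or mutation id, rule)`` entries.
    """
    df = raw.copy().reset_index(drop=True)
    report = []
    keep = np.ones(len(df), dtype=bool)

    for i, row in df.iterrows():
        bad = None
        for col in REQUIRED_COLUMNS:
            if col not in row or pd.isna(row[col]):
                bad = f"malformed row: missing {col}"
                break
        if bad is None and not np.isfinite(float(row["ddg_exp"])):
            bad = "malformed row: non-finite ddg_exp"
        if bad is None and str(row["wt_aa"]) == str(row["mut_aa"]):
            bad = "malformed row: identical wild-type and mutant residue"
        if bad:
            keep[i] = False
            report.append((i, bad))

    def reject(mask, rule):
        for i in np.nonzero(mask & keep)[0]:
            report.append((int(i), rule))
        keep[mask] = False

    if "interface_modified" in df:
        reject(df["interface_modified"].fillna(False).astype(bool).to_numpy(),
               "modified residues at binding interface")
    if "protein_length" in df:
        reject((df["protein_length"].astype(float) < 20).to_numpy(),
               "protein length < 20")
    if "rna_length" in df:
        reject((df["rna_length"].astype(float) < 5).to_numpy(),
               "RNA length < 5")
    if "metal_site" in df:
        reject(df["metal_site"].fillna(False).astype(bool).to_numpy(),
               "mutation at metal coordination site")
    if "rna_seq_structure" in df and "rna_seq_assay" in df:
        for i, row in df.iterrows():
            if not keep[i]:
                continue
            sa, sb = row["rna_seq_structure"], row["rna_seq_assay"]
            if isinstance(sa, str) and isinstance(sb, str) and sa and sb:
                if rna_identity(sa, sb) < similarity_threshold:
                    keep[i] = False
                    report.append((int(i), "RNA sequence similarity < 80%"))

    df = df[keep].reset_index(drop=True)

    # multi-measurement consolidation
    key_cols = ["pdb_id", "protein_chain", "position", "wt_aa", "mut_aa"]
    rows = []
    for key, grp in df.groupby(key_cols, sort=False):
        if len(grp) == 1:
            rows.append(grp.iloc[0])
            continue
        vals = grp["ddg_exp"].astype(float)
        mut_id = ":".join(map(str, key))
        if vals.max() - vals.min() < 1.0:
            row = grp.iloc[0].copy()
            row["ddg_exp"] = float(vals.mean())
            rows.append(row)
            report.append((mut_id,
                           f"averaged {len(grp)} measurements"))
        else:
            report.append((mut_id,
                           "discordant repeat measurements (range >= 1)"))
    curated = pd.DataFrame(rows).reset_index(drop=True)
    return curated, report
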