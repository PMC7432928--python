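"""Feature assembly and the multiple linear regression scoring function.

The predicted binding-affinity change of a mutation is a linear combination
of 11 features (three energy terms, five SASA/structure terms, three
sequence terms):

    ddG_pred = b0 + sum_i b_i * x_i

Coefficients are obtained by ordinary least squares on a training table of
experimentally measured ddG values; per-coefficient t-test p-values,
|t| importance and variance inflation factors are reported as diagnostics.
The sign convention is positive = binding-affinity decreasing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from . import energy, geometry, network, sequence
from .minimize import MinimizationSettings, minimize
from .mutate import MutationSpec, build_mutant, complete_structure
from .sasa import compute_sasa
from .secondary import assign_secondary_structure
from .structure import extract_partner

__all__ = ["FEATURE_NAMES", "FeatureVector", "TrainedModel", "DatasetRecord",
           "WildTypeContext", "featurize", "fit", "predict",
           "RankDeficiencyError"]

FEATURE_NAMES = [
    "dd_evdw", "dd_evdw_re", "dd_eelec", "n_inter", "r_l_sa", "closeness",
    "delta_sa", "p_coil", "delta_omh", "delta_p_fwy", "delta_p_krde",
]


class RankDeficiencyError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """The 11 named predictors for one mutation, in canonical order."""
    dd_evdw: float
    dd_evdw_re: float
    dd_eelec: float
    n_inter: float
    r_l_sa: float
    closeness: float
    delta_sa: float
    p_coil: float
    delta_omh: float
    delta_p_fwy: float
    delta_p_krde: float

    def __post_init__(self):
        for name in FEATURE_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"feature {name} is not finite")

    def as_array(self):
        return np.array([getattr(self, n) for n in FEATURE_NAMES])

    def as_dict(self):
        return {n: getattr(self, n) for n in FEATURE_NAMES}


@dataclass
class DatasetRecord:
    pdb_id: str
    mutation: MutationSpec
    ddg_exp: float
    alanine_scanning: bool = False
    interfacial: bool | None = None
    rna_type: str | None = None
    features: FeatureVector | None = None


@dataclass
class TrainedModel:
    """OLS fit: intercept + 11 coefficients with diagnostics."""
    intercept: float
    coefficients: dict
    pvalues: dict = field(default_factory=dict)
    vif: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)  # |t| statistic
    n_obs: int = 0
    residual_sd: float = float("nan")
    training_fingerprint: str = ""

    def __post_init__(self):
        missing = [n for n in FEATURE_NAMES if n not in self.coefficients]
        if missing:
            raise ValueError(f"model lacks coefficients for {missing}")

    def to_json(self, path=None):
        payload = {
            "format": "priddg-linear-model-v1",
            "intercept": self.intercept,
            "coefficients": {k: self.coefficients[k] for k in FEATURE_NAMES},
            "pvalues": self.pvalues,
            "vif": self.vif,
            "importance": self.importance,
            "n_obs": self.n_obs,
            "residual_sd": self.residual_sd,
            "training_fingerprint": self.training_fingerprint,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path):
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            pvalues=payload.get("pvalues", {}),
            vif=payload.get("vif", {}),
            importance=payload.get("importance", {}),
            n_obs=payload.get("n_obs", 0),
            residual_sd=payload.get("residual_sd", float("nan")),
            training_fingerprint=payload.get("training_fingerprint", ""),
        )


class WildTypeContext:
    """Wild-type-only computations shared by all mutations of one complex.

    Minimizing the wild type and computing its SASA, secondary structure,
    interface set and residue network once makes each additional mutation of
    the same complex much cheaper than the first.
    """

    def __init__(self, wt, settings=None, params=None, probe=1.4,
                 n_points=960):
        self.settings = settings or MinimizationSettings()
        self.params = params
        self.probe = probe
        self.n_points = n_points
        completed, _ = complete_structure(wt)
        self.wt_initial = completed
        self.wt_min = minimize(completed, self.settings, params)
        self.sasa_complex = compute_sasa(self.wt_min, probe, n_points)
        self.wt_protein = extract_partner(self.wt_min, 1)
        self.sasa_protein = compute_sasa(self.wt_protein, probe, n_points)
        self.sasa_rna = compute_sasa(extract_partner(self.wt_min, 2),
                                     probe, n_points)
        self.interface = geometry.interface_residues(
            self.wt_min, sasa_complex=self.sasa_complex,
            sasa_p1=self.sasa_protein, sasa_p2=self.sasa_rna)
        self.n_inter = geometry.n_inter(self.wt_min, interface=self.interface)
        self.r_l_sa = geometry.ratio_length_sasa(self.wt_protein,
                                                 sasa=self.sasa_protein)
        self.ss = assign_secondary_structure(self.wt_min)
        self.graph = network.build_network(self.wt_min)
        self.max_asa = geometry.load_max_asa()
        modified = set(map(tuple, wt.provenance.get("modified_residues", [])))
        bad = modified & self.interface
        if bad:
            raise ValueError(
                "complex rejected: modified residues at the binding "
                f"interface: {sorted(bad)}")

    def is_interfacial(self, site_key):
        return site_key in self.interface


def featurize(wt, spec, settings=None, params=None, context=None):
    """Compute the 11-feature vector for one mutation of a complex.

    Builds the mutant from the wild type, minimizes both with
    backbone-restrained minimization, and evaluates every feature.
    Deterministic for fixed inputs and settings. Pass a
    :class:`WildTypeContext` to reuse wild-type-only work across mutations
    of the same complex.
    """
    if context is None:
        context = WildTypeContext(wt, settings, params)
    ctx = context
    site_key = spec.site_key

    mut = build_mutant(ctx.wt_initial, spec)
    mut_min = minimize(mut, ctx.settings, ctx.params)
    mut_protein = extract_partner(mut_min, 1)

    ddvdw = energy.dd_evdw(ctx.wt_min, mut_min, ctx.params)
    ddrep = energy.dd_evdw_rep(ctx.wt_min, mut_min, site_key, ctx.params)
    ddelec = energy.dd_eelec(ctx.wt_min, mut_min, site_key, ctx.params)

    dsa = geometry.delta_sa(
        ctx.wt_protein, mut_protein, site_key,
        probe=ctx.probe, n_points=ctx.n_points, sasa_wt=ctx.sasa_protein)
    pc = geometry.p_coil(ctx.wt_min, spec.chain,
                         sasa_complex=ctx.sasa_complex, ss=ctx.ss,
                         max_asa=ctx.max_asa)
    clo = network.closeness(ctx.graph, site_key)

    chain_seq = ctx.wt_min.chain_sequence(spec.chain)
    chain_keys = [r.key for r in ctx.wt_min.chain_residues(spec.chain)]
    pos_index = chain_keys.index(site_key)
    domh = sequence.delta_omh(spec.wt_aa, spec.mut_aa)
    dfwy, dkrde = sequence.composition_deltas(chain_seq, pos_index,
                                              spec.wt_aa, spec.mut_aa)

    return FeatureVector(
        dd_evdw=ddvdw, dd_evdw_re=ddrep, dd_eelec=ddelec,
        n_inter=float(ctx.n_inter), r_l_sa=ctx.r_l_sa, closeness=clo,
        delta_sa=dsa, p_coil=pc, delta_omh=domh, delta_p_fwy=dfwy,
        delta_p_krde=dkrde,
    )


def _design_matrix(table):
    if isinstance(table, pd.DataFrame):
        X = table[FEATURE_NAMES].to_numpy(dtype=float)
        y = table["ddg_exp"].to_numpy(dtype=float)
    else:  # sequence of DatasetRecord with features
        X = np.array([rec.features.as_array() for rec in table])
        y = np.array([rec.ddg_exp for rec in table])
    return X, y


def fit(table):
    """Ordinary least squares of experimental ddG on the 11 features.

    ``table`` is a DataFrame with the feature columns and ``ddg_exp``, or a
    sequence of featurized :class:`DatasetRecord`. Raises
    :class:`RankDeficiencyError` naming collinear columns when the design
    matrix is rank-deficient.
    """
    X, y = _design_matrix(table)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations, got {n}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the training table")

    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns involved in exact collinearity via QR pivoting
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        bad = [FEATURE_NAMES[i - 1] for i in range(1, exog.shape[1])
               if diag[i] < 1e-8 * diag.max()]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (collinear columns: {bad})")

    res = sm.OLS(y, exog).fit()
    coefs = dict(zip(FEATURE_NAMES, res.params[1:]))
    pvals = dict(zip(FEATURE_NAMES, res.pvalues[1:]))
    tstats = dict(zip(FEATURE_NAMES, np.abs(res.tvalues[1:])))
    vifs = {
        name: float(variance_inflation_factor(exog, i + 1))
        for i, name in enumerate(FEATURE_NAMES)
    }
    fingerprint = hashlib.sha256(
        np.ascontiguousarray(np.column_stack([X, y])).tobytes()).hexdigest()[:16]
    return TrainedModel(
        intercept=float(res.params[0]),
        coefficients={k: float(v) for k, v in coefs.items()},
        pvalues={k: float(v) for k, v in pvals.items()},
        vif=vifs,
        importance={k: float(v) for k, v in tstats.items()},
        n_obs=n,
        residual_sd=float(np.sqrt(res.mse_resid)),
        training_fingerprint=fingerprint,
    )


def predict(model, features):
    """ddG prediction (kcal/mol) for one FeatureVector, a mapping of the 11
    named features, or a DataFrame with the feature columns."""
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_NAMES].to_numpy(dtype=float)
        beta = np.array([model.coefficients[n] for n in FEATURE_NAMES])
        return model.intercept + X @ beta
    if isinstance(features, FeatureVector):
        vals = features.as_dict()
    else:
        vals = dict(features)
        missing = [n for n in FEATURE_NAMES if n not in vals]
        if missing:
            raise KeyError(f"feature(s) missing from input: {missing}")
    return model.intercept + sum(
        model.coefficients[n] * vals[n] for n in FEATURE_NAMES)
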