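"""Phenotype assignment, shifter classification and responder selection.

Animals are clustered into *phasic* (fast decay, sustained freezing near
baseline) and *sustained* (slow decay, high late freezing) responders
from the decay features.  The component whose mean of the
``sustained_mean`` feature is larger is labelled sustained — the labels
depend only on component statistics, never on component order.  Animals
whose assignment differs between the first two retrievals are
"shifters": sustained-to-phasic shifts indicate safety learning,
phasic-to-sustained shifts threat generalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import MixtureModel, em_fit, model_bic

CONSISTENCY_CATEGORIES = (
    "consistent_phasic",
    "consistent_sustained",
    "shifter_sustained_to_phasic",
    "shifter_phasic_to_sustained",
    "unclassified",
)


def assign_phenotypes(model: MixtureModel, features: pd.DataFrame,
                      session: str | None = None) -> pd.DataFrame:
    """Assign each animal to a phenotype by maximum responsibility.

    Parameters
    ----------
    model
        A fitted two-component mixture over the feature matrix columns.
    features
        DataFrame indexed by animal_id with the columns the model was
        fitted on (must include ``sustained_mean``).
    session
        Optional session label stored in the output.

    Returns a DataFrame with columns ``animal_id, session, label,
    posterior, tied`` where posterior is the winning responsibility
    (in [0.5, 1] for k = 2).  An exact 0.5 tie is assigned to sustained
    (the conservative direction for an anxiety screen) and flagged.
    """
    if model.k != 2:
        raise ValueError("phenotype assignment requires a two-component model")
    if "sustained_mean" not in features.columns:
        raise ValueError("features must include a 'sustained_mean' column")
    if model.means.shape[1] != features.shape[1]:
        raise ValueError("model dimensionality does not match feature matrix")

    resp = model.responsibilities(features.to_numpy(dtype=float))
    sus_col = list(features.columns).index("sustained_mean")
    sustained_comp = int(np.argmax(model.means[:, sus_col]))

    p_sustained = resp[:, sustained_comp]
    tied = np.isclose(p_sustained, 0.5, rtol=0.0, atol=1e-12)
    labels = np.where(p_sustained >= 0.5, "sustained", "phasic")
    labels[tied] = "sustained"  # exact tie: conservative direction
    posterior = np.maximum(p_sustained, 1.0 - p_sustained)
    posterior[tied] = 0.5
    if tied.any():
        warnings.warn(
            f"{int(tied.sum())} animal(s) had responsibility exactly 0.5; "
            "assigned to sustained", stacklevel=2,
        )
    return pd.DataFrame(
        {
            "animal_id": features.index.astype(str),
            "session": session,
            "label": labels,
            "posterior": posterior,
            "tied": tied,
        }
    ).reset_index(drop=True)


def classify_consistency(mr1: pd.DataFrame, mr2: pd.DataFrame) -> pd.DataFrame:
    """Cross-retrieval consistency from the MR1 and MR2 assignments.

    Returns a DataFrame ``animal_id, category`` with categories
    consistent_phasic / consistent_sustained / shifter_sustained_to_phasic
    / shifter_phasic_to_sustained; animals missing from either session
    are ``unclassified``.
    """
    a = mr1.set_index("animal_id")["label"]
    b = mr2.set_index("animal_id")["label"]
    ids = a.index.union(b.index)
    cats = []
    for animal in ids:
        l1 = a.get(animal)
        l2 = b.get(animal)
        if l1 is None or l2 is None:
            cats.append("unclassified")
        elif l1 == l2:
            cats.append(f"consistent_{l1}")
        elif l1 == "sustained":
            cats.append("shifter_sustained_to_phasic")
        else:
            cats.append("shifter_phasic_to_sustained")
    return pd.DataFrame({"animal_id": ids.astype(str), "category": cats}).reset_index(drop=True)


def shifter_rates(consistency: pd.DataFrame) -> dict[str, float]:
    """Observed shift proportions, conditioned on the MR1 phenotype.

    sustained_to_phasic is the fraction of MR1-sustained animals that
    shifted; phasic_to_sustained likewise for MR1-phasic animals.
    """
    cat = consistency["category"]
    n_sus = int(((cat == "consistent_sustained") | (cat == "shifter_sustained_to_phasic")).sum())
    n_pha = int(((cat == "consistent_phasic") | (cat == "shifter_phasic_to_sustained")).sum())
    return {
        "sustained_to_phasic": (cat == "shifter_sustained_to_phasic").sum() / n_sus if n_sus else np.nan,
        "phasic_to_sustained": (cat == "shifter_phasic_to_sustained").sum() / n_pha if n_pha else np.nan,
        "n_sustained_mr1": n_sus,
        "n_phasic_mr1": n_pha,
    }


def cluster_cohort(sessions, session_label: str = "MR1", per_sex: bool = True,
                   covariance_family: str = "diagonal", scale: bool = False,
                   n_restarts: int = 20, seed: int = 0,
                   floor_eps: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Full phenotyping step for one retrieval: fit curves, cluster, assign.

    The cohort default clusters each sex separately (the sexes differ in
    sustained-phase freezing, and the study's cohorts were single-sex)
    with a diagonal covariance family: the decay features live on
    incommensurate scales and their within-phenotype dependence is a
    curved function of the decay rate, which an unconstrained covariance
    ellipse overfits at cohort-sized n — systematically misassigning
    animals with intermediate decay rates.  Set ``per_sex=False`` /
    ``covariance_family='full'`` to override; ``scale=True`` z-scores
    the features first.

    Returns ``(assignments, models)`` where models maps the group key
    ("female"/"male" or "all") to its fitted MixtureModel.
    """
    from .decay import DEFAULT_FLOOR_EPS, build_features, fit_cohort

    subset = [s for s in sessions if s.session == session_label]
    if not subset:
        raise ValueError(f"no sessions with label {session_label!r}")
    groups = ({sex: [s for s in subset if s.sex == sex] for sex in ("female", "male")}
              if per_sex else {"all": subset})
    parts, models = [], {}
    for key, group in groups.items():
        if not group:
            continue
        X = build_features(fit_cohort(group, floor_eps=floor_eps or DEFAULT_FLOOR_EPS))
        Xf = (X - X.mean()) / X.std() if scale else X
        model = em_fit(Xf, k=2, covariance_family=covariance_family,
                       n_restarts=n_restarts, seed=seed)
        models[key] = model
        parts.append(assign_phenotypes(model, Xf, session=session_label))
    return pd.concat(parts, ignore_index=True), models


# ---------------------------------------------------------------------------
# greedy variable selection for model-based clustering

@dataclass
class FeatureSelectionResult:
    """Outcome of the greedy forward/backward clustering-variable search.

    ``evidence`` is BIC(one component) − BIC(best two-component mixture)
    on the selected subset: positive values favour a two-cluster
    structure.  ``supported`` is False when no subset produced positive
    evidence ("no clustering support").
    """

    selected: list[str]
    evidence: float
    supported: bool
    trace: list[tuple[str, str, float]] = field(default_factory=list)


def _clustering_evidence(features: pd.DataFrame, cols: list[str], seed: int,
                         n_restarts: int, covariance_family: str) -> float:
    from .mixture import EMConvergenceError

    sub = features[cols]
    m1 = em_fit(sub, k=1, covariance_family=covariance_family, seed=seed)
    try:
        m2 = em_fit(sub, k=2, covariance_family=covariance_family,
                    n_restarts=n_restarts, seed=seed)
    except EMConvergenceError:
        # no stable two-component fit on this subset: no clustering evidence
        return float("-inf")
    n = len(sub)
    return model_bic(m1, n) - model_bic(m2, n)


def greedy_feature_selection(features: pd.DataFrame, max_features: int | None = None,
                             seed: int = 0, n_restarts: int = 10,
                             covariance_family: str = "full") -> FeatureSelectionResult:
    """Forward-then-backward greedy search for clustering variables.

    The forward pass adds, and the backward pass removes, the feature
    whose inclusion/exclusion most improves the clustering-evidence
    score; the search stops when no step improves.  Constant columns are
    excluded before the search.  Deterministic given ``seed``.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    candidates = []
    for c in features.columns:
        if np.ptp(features[c].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"constant feature {c!r} excluded from selection", stacklevel=2)
        else:
            candidates.append(c)
    if not candidates:
        return FeatureSelectionResult([], float("-inf"), False)
    if max_features is None:
        max_features = len(candidates)

    selected: list[str] = []
    evidence = float("-inf")
    trace: list[tuple[str, str, float]] = []

    # forward pass
    while len(selected) < max_features:
        best_col, best_ev = None, evidence
        for c in candidates:
            if c in selected:
                continue
            ev = _clustering_evidence(features, selected + [c], seed, n_restarts,
                                      covariance_family)
            if ev > best_ev:
                best_col, best_ev = c, ev
        if best_col is None:
            break
        selected.append(best_col)
        evidence = best_ev
        trace.append(("add", best_col, evidence))

    # backward pass
    improved = True
    while improved and len(selected) > 1:
        improved = False
        for c in list(selected):
            remaining = [s for s in selected if s != c]
            ev = _clustering_evidence(features, remaining, seed, n_restarts,
                                      covariance_family)
            if ev > evidence:
                selected = remaining
                evidence = ev
                trace.append(("remove", c, evidence))
                improved = True
                break

    supported = bool(selected) and evidence > 0
    if not supported:
        warnings.warn("no clustering support: best subset has non-positive evidence",
                      stacklevel=2)
    return FeatureSelectionResult(selected, evidence, supported, trace)


# ---------------------------------------------------------------------------
# extreme-responder selection

@dataclass
class SelectionResult:
    """Selected animal ids per phenotype plus the full ranking table."""

    sustained: list[str]
    phasic: list[str]
    table: pd.DataFrame


def _take(ranked: pd.DataFrame, group: str, n: int) -> list[str]:
    sub = ranked[ranked["group"] == group]
    if len(sub) < n:
        raise ValueError(
            f"cannot select {n} {group} animals: only {len(sub)} available"
        )
    return sub["animal_id"].head(n).tolist()


def select_extremes(assignments: pd.DataFrame, fits: pd.DataFrame,
                    n_per_group: int, mode: str = "mr1_profile",
                    consistency: pd.DataFrame | None = None,
                    metrics: pd.DataFrame | None = None) -> SelectionResult:
    """Select the n most extreme animals per phenotype for profiling.

    mode ``mr1_profile``
        Rank sustained candidates by sustained freezing descending
        (decay rate ascending breaks ties) and phasic candidates by
        sustained freezing ascending (decay rate descending breaks
        ties) — i.e. high sustained freezing / slow decay versus low
        sustained freezing / fast decay.
    mode ``consistency_oft``
        Restrict to animals with a consistent phenotype across MR1 and
        MR2, then rank sustained animals by open-field periphery time
        descending and phasic animals ascending (avoidance versus
        approach in the arena).
    """
    if mode not in ("mr1_profile", "consistency_oft"):
        raise ValueError(f"unknown selection mode {mode!r}")

    if mode == "mr1_profile":
        merged = assignments.merge(
            fits[["animal_id", "sustained_mean", "b"]], on="animal_id", how="inner"
        )
        merged["group"] = merged["label"]
        sus = merged[merged["group"] == "sustained"].sort_values(
            ["sustained_mean", "b"], ascending=[False, True], kind="mergesort")
        pha = merged[merged["group"] == "phasic"].sort_values(
            ["sustained_mean", "b"], ascending=[True, False], kind="mergesort")
        ranked = pd.concat([sus, pha], ignore_index=True)
        ranked["rank"] = ranked.groupby("group").cumcount() + 1
    else:
        if consistency is None or metrics is None:
            raise ValueError("consistency_oft mode requires consistency labels and metrics")
        cons = consistency[consistency["category"].str.startswith("consistent_")].copy()
        cons["group"] = cons["category"].str.removeprefix("consistent_")
        merged = cons.merge(metrics[["animal_id", "oft_periphery_s"]],
                            on="animal_id", how="left")
        missing = merged["oft_periphery_s"].isna()
        if missing.any():
            dropped = merged.loc[missing, "animal_id"].tolist()
            warnings.warn(f"animals without OFT periphery time excluded: {dropped}",
                          stacklevel=2)
            merged = merged[~missing]
        sus = merged[merged["group"] == "sustained"].sort_values(
            "oft_periphery_s", ascending=False, kind="mergesort")
        pha = merged[merged["group"] == "phasic"].sort_values(
            "oft_periphery_s", ascending=True, kind="mergesort")
        ranked = pd.concat([sus, pha], ignore_index=True)
        ranked["rank"] = ranked.groupby("group").cumcount() + 1

    return SelectionResult(
        sustained=_take(ranked, "sustained", n_per_group),
        phasic=_take(ranked, "phasic", n_per_group),
        table=ranked.reset_index(drop=True),
    )
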