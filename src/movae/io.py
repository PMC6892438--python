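"""Reading, validation, feature selection, scaling and stacking of omics matrices.

Matrices are stored features x samples (rows = genes), mirroring the usual
m_ij / c_ij indexing of binary mutation matrices and gene-level copy-number
segment means. All on-disk formats are delimited text: row 1 holds sample
ids, column 1 holds feature ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODALITIES = ("expression", "mutation", "cnv")

#: Variant-effect strings treated as protein-altering when binarizing long-format
#: mutation tables (lower-cased before comparison). A simplified MAF vocabulary.
DEFAULT_NONSYNONYMOUS = frozenset(
    {
        "missense_mutation",
        "missense",
        "nonsense_mutation",
        "nonsense",
        "frame_shift_del",
        "frame_shift_ins",
        "frameshift",
        "in_frame_del",
        "in_frame_ins",
        "splice_site",
        "nonstop_mutation",
        "translation_start_site",
    }
)


class OmicsValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids, kind: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise OmicsValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """A single-modality feature x sample matrix.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
    feature_ids, sample_ids : ordered unique identifiers
    modality : one of ``"expression"``, ``"mutation"``, ``"cnv"``
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.modality not in MODALITIES:
            raise OmicsValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.values.ndim != 2:
            raise OmicsValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise OmicsValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise OmicsValidationError("matrix contains missing or non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: list[str]) -> "OmicsMatrix":
        idx = [self.feature_ids.index(f) for f in keep]
        return replace(self, values=self.values[idx], feature_ids=list(keep))


@dataclass
class OmicsStack:
    """Row-stacked multi-omics input x = [x_expression; x_mutation; x_cnv].

    All member matrices share the same samples in the same order; rows keep a
    record of which modality they came from.
    """

    matrices: list[OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise OmicsValidationError("cannot stack an empty list of matrices")
        ref = self.matrices[0].sample_ids
        for m in self.matrices[1:]:
            if m.sample_ids != ref:
                raise OmicsValidationError(
                    "all matrices in a stack must share identical sample ids in order"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[0].sample_ids

    @property
    def values(self) -> np.ndarray:
        """Stacked (sum of features) x samples matrix."""
        return np.vstack([m.values for m in self.matrices])

    @property
    def feature_ids(self) -> list[str]:
        return [f for m in self.matrices for f in m.feature_ids]

    @property
    def modality_of_row(self) -> list[str]:
        return [m.modality for m in self.matrices for _ in m.feature_ids]

    @property
    def n_features(self) -> int:
        return sum(m.n_features for m in self.matrices)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def modality(self, name: str) -> OmicsMatrix:
        for m in self.matrices:
            if m.modality == name:
                return m
        raise KeyError(name)

    def subset_samples(self, idx) -> "OmicsStack":
        idx = np.asarray(idx)
        mats = [
            replace(
                m,
                values=m.values[:, idx],
                sample_ids=[m.sample_ids[i] for i in idx],
            )
            for m in self.matrices
        ]
        return OmicsStack(mats)


@dataclass
class ScalingModel:
    """Frozen per-feature transform: z-score (population sd), then min-max to [0,1].

    Degenerate features (zero spread, or a single distinct z-score) map to 0.5 so
    that feature indices stay aligned with network and gene-set annotations.
    """

    feature_ids: list[str]
    center: np.ndarray
    spread: np.ndarray
    z_min: np.ndarray
    z_max: np.ndarray

    def apply(self, X: OmicsMatrix) -> OmicsMatrix:
        if X.feature_ids != self.feature_ids:
            raise OmicsValidationError("feature ids do not match the fitted ScalingModel")
        return replace(X, values=self.apply_values(X.values))

    def apply_values(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        spread = np.where(self.spread > 0, self.spread, 1.0)
        z = (values - self.center[:, None]) / spread[:, None]
        span = self.z_max - self.z_min
        ok = (self.spread > 0) & (span > 0)
        out = np.full_like(z, 0.5)
        safe_span = np.where(span > 0, span, 1.0)
        scaled = (z - self.z_min[:, None]) / safe_span[:, None]
        out[ok] = scaled[ok]
        return out


@dataclass
class JointScalingModel:
    """Two-step cohort harmonisation: per-cohort scaling, then joint rescaling.

    Step 1 removes per-cohort location/scale (and with it additive cohort
    offsets); step 2 maps the concatenated cohorts to a common [0,1] range.
    """

    cohort_models: dict[str, ScalingModel]
    combined: ScalingModel

    def apply(self, X: OmicsMatrix, cohort: str) -> OmicsMatrix:
        step1 = self.cohort_models[cohort].apply(X)
        return self.combined.apply(step1)


def validate_mutation_binary(X: OmicsMatrix) -> None:
    """Assert that a raw mutation matrix is strictly 0/1.

    Applies to matrices as read or binarized; network smoothing and scaling
    legitimately produce continuous values downstream.
    """
    bad = ~np.isin(X.values, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise OmicsValidationError(
            "mutation matrix must be binary; found "
            f"{X.values[i, j]!r} at ({X.feature_ids[i]}, {X.sample_ids[j]})"
        )


def read_matrix(path, modality: str, delimiter: str = "\t") -> OmicsMatrix:
    """Read a feature x sample matrix from delimited text.

    Row 1 = sample ids, column 1 = feature ids. Duplicate ids and non-numeric
    cells are rejected; mutation matrices must be binary.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise OmicsValidationError(f"non-numeric value in {path}: {exc}") from exc
    X = OmicsMatrix(
        values=values,
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        modality=modality,
    )
    if modality == "mutation":
        validate_mutation_binary(X)
    return X


def write_matrix(X: OmicsMatrix, path, delimiter: str = "\t") -> None:
    # %.17g guarantees float64 round-trips exactly through text
    X.to_frame().to_csv(path, sep=delimiter, index_label="feature", float_format="%.17g")


def binarize_mutations(
    records: pd.DataFrame,
    samples: list[str],
    nonsynonymous_effects=DEFAULT_NONSYNONYMOUS,
    genes: list[str] | None = None,
) -> OmicsMatrix:
    """Collapse a long (gene, sample, effect) table into a binary mutation matrix.

    ``m_ij = 1`` iff gene i carries at least one record with a protein-altering
    effect in sample j; synonymous records and repeat hits contribute nothing
    further.
    """
    effects = {e.lower() for e in nonsynonymous_effects}
    samples = [str(s) for s in samples]
    if records.empty:
        warnings.warn("empty mutation record table; returning an all-zero matrix")
        gene_list = list(genes) if genes is not None else []
        return OmicsMatrix(
            np.zeros((len(gene_list), len(samples))), gene_list, samples, "mutation"
        )
    required = {"gene", "sample", "effect"}
    if not required.issubset(records.columns):
        raise OmicsValidationError(f"mutation table needs columns {sorted(required)}")
    unknown = set(records["sample"].astype(str)) - set(samples)
    if unknown:
        raise OmicsValidationError(
            f"mutation records reference unknown sample ids: {sorted(unknown)[:5]}"
        )
    hits = records[records["effect"].astype(str).str.lower().isin(effects)]
    if genes is None:
        gene_list = sorted(records["gene"].astype(str).unique())
    else:
        gene_list = [str(g) for g in genes]
    values = np.zeros((len(gene_list), len(samples)))
    gene_idx = {g: i for i, g in enumerate(gene_list)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    for g, s in zip(hits["gene"].astype(str), hits["sample"].astype(str)):
        if g in gene_idx:
            values[gene_idx[g], sample_idx[s]] = 1.0
    return OmicsMatrix(values, gene_list, samples, "mutation")


def mad(values: np.ndarray, axis: int = 1) -> np.ndarray:
    """Median absolute deviation (raw, unscaled) along ``axis``."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def select_features_mad(X: OmicsMatrix, n_top: int) -> OmicsMatrix:
    """Keep the n_top features with largest MAD, computed on raw values.

    Ties at the selection boundary break lexicographically by feature id;
    surviving features keep their original order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > X.n_features:
        raise ValueError(f"n_top={n_top} exceeds feature count {X.n_features}")
    scores = mad(X.values)
    order = sorted(range(X.n_features), key=lambda i: (-scores[i], X.feature_ids[i]))
    chosen = sorted(order[:n_top])  # restore original feature order
    return replace(
        X,
        values=X.values[chosen],
        feature_ids=[X.feature_ids[i] for i in chosen],
    )


def fit_scaling(X: OmicsMatrix) -> ScalingModel:
    if X.n_samples < 2:
        raise OmicsValidationError("scaling requires at least 2 samples")
    center = X.values.mean(axis=1)
    spread = X.values.std(axis=1)  # population form (denominator n)
    safe = np.where(spread > 0, spread, 1.0)
    z = (X.values - center[:, None]) / safe[:, None]
    return ScalingModel(
        feature_ids=list(X.feature_ids),
        center=center,
        spread=spread,
        z_min=z.min(axis=1),
        z_max=z.max(axis=1),
    )


def scale_features(X: OmicsMatrix) -> tuple[OmicsMatrix, ScalingModel]:
    """Z-score each feature then map affinely to [0,1]; constants map to 0.5."""
    model = fit_scaling(X)
    return model.apply(X), model


def joint_scale(
    cohort_a: OmicsMatrix, cohort_b: OmicsMatrix, names: tuple[str, str] = ("a", "b")
) -> tuple[OmicsMatrix, JointScalingModel]:
    """Scale two cohorts individually, concatenate, and rescale jointly.

    Removes additive per-cohort batch offsets so tumors and cell lines (or any
    two cohorts) live on a shared [0,1] scale; the returned model maps new
    samples of either cohort consistently.
    """
    if cohort_a.feature_ids != cohort_b.feature_ids:
        raise OmicsValidationError("joint scaling requires identical feature ids")
    if set(cohort_a.sample_ids) & set(cohort_b.sample_ids):
        raise OmicsValidationError("cohorts must have disjoint sample ids")
    scaled_a, model_a = scale_features(cohort_a)
    scaled_b, model_b = scale_features(cohort_b)
    combined = OmicsMatrix(
        np.hstack([scaled_a.values, scaled_b.values]),
        list(cohort_a.feature_ids),
        list(cohort_a.sample_ids) + list(cohort_b.sample_ids),
        cohort_a.modality,
    )
    scaled, model_c = scale_features(combined)
    joint = JointScalingModel(
        cohort_models={names[0]: model_a, names[1]: model_b}, combined=model_c
    )
    return scaled, joint


def stack_modalities(matrices: list[OmicsMatrix]) -> OmicsStack:
    """Stack per-modality matrices row-wise, expression -> mutation -> cnv."""
    order = {m: i for i, m in enumerate(MODALITIES)}
    ordered = sorted(matrices, key=lambda m: order[m.modality])
    return OmicsStack(ordered)


def concat_samples(a: OmicsStack, b: OmicsStack) -> OmicsStack:
    """Pool two cohorts column-wise (same features/modalities, disjoint samples)."""
    if a.feature_ids != b.feature_ids:
        raise OmicsValidationError("stacks must share identical features to pool samples")
    if set(a.sample_ids) & set(b.sample_ids):
        raise OmicsValidationError("pooled cohorts must have disjoint sample ids")
    mats = [
        replace(
            ma,
            values=np.hstack([ma.values, mb.values]),
            sample_ids=list(ma.sample_ids) + list(mb.sample_ids),
        )
        for ma, mb in zip(a.matrices, b.matrices)
    ]
    return OmicsStack(mats)


def scale_stack(stack: OmicsStack) -> tuple[OmicsStack, list[ScalingModel]]:
    """Scale every member matrix of a stack to [0,1], returning per-matrix models."""
    scaled, models = [], []
    for m in stack.matrices:
        s, model = scale_features(m)
        scaled.append(s)
        models.append(model)
    return OmicsStack(scaled), models
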