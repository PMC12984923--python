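"""The 39-feature entropy bank: fixed-order registry, dispatch and extraction.

Features F1..F26 are single-signal measures of the primary signal; F27..F39
are cross measures that additionally consume a reference signal (by default
the complementary-region signal from the same source image).  The tolerance
for template-matching measures is r = 0.2 x SD of the primary signal, except
range entropy whose ratio metric uses a fixed r = 0.2.  None of the embedded
parameters are dictated by the classification task; each default follows the
measure's original publication and can be overridden via ``params``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..errors import InsufficientLengthError, InvalidInputError, RegistryError
from ..preprocess import RegionClass
from . import cross as xent
from . import single as sent

FEATURE_IDS = tuple(f"F{i}" for i in range(1, 40))


@dataclass
class SamplePair:
    """Primary + reference 1-D signals with a class label and source identity.

    Unequal lengths are truncated to the shorter signal (recorded in
    ``truncated``) so the cross measures see aligned templates.
    """

    primary: np.ndarray
    reference: np.ndarray
    class_label: RegionClass
    source_image_id: str = ""
    truncated: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, dtype=float).ravel()
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        if not (np.all(np.isfinite(self.primary)) and np.all(np.isfinite(self.reference))):
            raise InvalidInputError("signals must be finite")
        n = min(self.primary.size, self.reference.size)
        if self.primary.size != self.reference.size:
            self.truncated = True
            self.primary = self.primary[:n]
            self.reference = self.reference[:n]


@dataclass
class FeatureVector:
    """Ordered 39-value descriptor keyed F1..F39."""

    values: np.ndarray
    class_label: RegionClass
    source_image_id: str = ""
    nonfinite_ids: tuple[str, ...] = ()
    capped_ids: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_IDS, self.values))


@dataclass(frozen=True)
class FeatureSpec:
    feature_id: str
    name: str
    family: str
    params: dict
    requires_reference: bool
    fn: Callable


def _r(pair: SamplePair, params: dict) -> float:
    return sent.default_tolerance(pair.primary, params.get("r_fraction", 0.2))


def _build_registry() -> dict[str, FeatureSpec]:
    def single(fid, name, family, params, fn):
        return FeatureSpec(fid, name, family, params, False, fn)

    def crossf(fid, name, family, params, fn):
        return FeatureSpec(fid, name, family, params, True, fn)

    specs = [
        single("F1", "Approximate Entropy (m=0)", "approximate", {"m": 0},
               lambda p, q: sent.approximate_entropy(p.primary, 0, _r(p, q))),
        single("F2", "Approximate Entropy (m=1)", "approximate", {"m": 1},
               lambda p, q: sent.approximate_entropy(p.primary, 1, _r(p, q))),
        single("F3", "Approximate Entropy (m=2)", "approximate", {"m": 2},
               lambda p, q: sent.approximate_entropy(p.primary, 2, _r(p, q))),
        single("F4", "Attention Entropy", "attention", {},
               lambda p, q: sent.attention_entropy(p.primary)),
        single("F5", "Bubble Entropy", "bubble", {"m": 10},
               lambda p, q: sent.bubble_entropy(p.primary, q.get("m", 10))),
        single("F6", "Composite Multiscale Entropy (time scale 1)", "multiscale",
               {"scale": 1, "m": 2},
               lambda p, q: sent.composite_multiscale_entropy(p.primary, 1, q.get("m", 2), _r(p, q))),
        single("F7", "Composite Multiscale Entropy (time scale 2)", "multiscale",
               {"scale": 2, "m": 2},
               lambda p, q: sent.composite_multiscale_entropy(p.primary, 2, q.get("m", 2), _r(p, q))),
        single("F8", "Composite Multiscale Entropy (time scale 3)", "multiscale",
               {"scale": 3, "m": 2},
               lambda p, q: sent.composite_multiscale_entropy(p.primary, 3, q.get("m", 2), _r(p, q))),
        single("F9", "Shannon Entropy", "histogram", {"n_bins": 256, "range": (0.0, 255.0)},
               lambda p, q: sent.shannon_entropy(p.primary, q.get("n_bins", 256),
                                                 q.get("range", (0.0, 255.0)))),
        single("F10", "Corrected Conditional Entropy", "conditional", {"m": 2, "n_bins": 6},
               lambda p, q: sent.corrected_conditional_entropy(p.primary, q.get("m", 2),
                                                               q.get("n_bins", 6))),
        single("F11", "Cosine Similarity Entropy", "cosine", {"m": 2, "r": 0.1},
               lambda p, q: sent.cosine_similarity_entropy(p.primary, q.get("m", 2),
                                                           q.get("r", 0.1))),
        single("F12", "Dispersion Entropy", "dispersion", {"m": 2, "c": 6, "tau": 1},
               lambda p, q: sent.dispersion_entropy(p.primary, q.get("m", 2), q.get("c", 6),
                                                    q.get("tau", 1))),
        single("F13", "Distribution Entropy", "distribution", {"m": 2, "n_bins": 512},
               lambda p, q: sent.distribution_entropy(p.primary, q.get("m", 2),
                                                      q.get("n_bins", 512))),
        single("F14", "Diversity Entropy", "diversity", {"m": 2, "n_bins": 5},
               lambda p, q: sent.diversity_entropy(p.primary, q.get("m", 2), q.get("n_bins", 5))),
        single("F15", "Entropy of Entropy", "entropy_of_entropy", {"window": 5, "n_levels": 5},
               lambda p, q: sent.entropy_of_entropy(p.primary, q.get("window", 5),
                                                    q.get("n_levels", 5))),
        single("F16", "Fuzzy Entropy (m=1)", "fuzzy", {"m": 1, "n_exp": 2.0},
               lambda p, q: sent.fuzzy_entropy(p.primary, 1, _r(p, q), q.get("n_exp", 2.0))),
        single("F17", "Fuzzy Entropy (m=2)", "fuzzy", {"m": 2, "n_exp": 2.0},
               lambda p, q: sent.fuzzy_entropy(p.primary, 2, _r(p, q), q.get("n_exp", 2.0))),
        single("F18", "Gridded Distribution Entropy", "gridded", {"n_grid": 3},
               lambda p, q: sent.gridded_distribution_entropy(p.primary, q.get("n_grid", 3))),
        single("F19", "Permutation Entropy", "permutation", {"m": 3, "tau": 1},
               lambda p, q: sent.permutation_entropy(p.primary, q.get("m", 3), q.get("tau", 1))),
        single("F20", "Phase Entropy", "phase", {"n_sectors": 4},
               lambda p, q: sent.phase_entropy(p.primary, q.get("n_sectors", 4))),
        single("F21", "Range Entropy", "range", {"m": 2, "r": 0.2},
               lambda p, q: sent.range_entropy(p.primary, q.get("m", 2), q.get("r", 0.2))),
        single("F22", "Sample Entropy (m=0)", "sample", {"m": 0},
               lambda p, q: sent.sample_entropy(p.primary, 0, _r(p, q))),
        single("F23", "Sample Entropy (m=1)", "sample", {"m": 1},
               lambda p, q: sent.sample_entropy(p.primary, 1, _r(p, q))),
        single("F24", "Sample Entropy (m=2)", "sample", {"m": 2},
               lambda p, q: sent.sample_entropy(p.primary, 2, _r(p, q))),
        single("F25", "Slope Entropy", "slope", {"m": 2, "gamma": 5.0, "delta": 0.001},
               lambda p, q: sent.slope_entropy(p.primary, q.get("m", 2), q.get("gamma", 5.0),
                                               q.get("delta", 0.001))),
        single("F26", "Spectral Entropy", "spectral", {},
               lambda p, q: sent.spectral_entropy(p.primary)),
        crossf("F27", "Cross-approximate Entropy (m=0)", "cross_approximate", {"m": 0},
               lambda p, q: xent.cross_approximate_entropy(p.primary, p.reference, 0, _r(p, q))),
        crossf("F28", "Cross-approximate Entropy (m=1)", "cross_approximate", {"m": 1},
               lambda p, q: xent.cross_approximate_entropy(p.primary, p.reference, 1, _r(p, q))),
        crossf("F29", "Cross-approximate Entropy (m=2)", "cross_approximate", {"m": 2},
               lambda p, q: xent.cross_approximate_entropy(p.primary, p.reference, 2, _r(p, q))),
        crossf("F30", "Corrected Cross-conditional Entropy", "cross_conditional",
               {"m": 2, "n_bins": 6},
               lambda p, q: xent.corrected_cross_conditional_entropy(p.primary, p.reference,
                                                                     q.get("m", 2),
                                                                     q.get("n_bins", 6))),
        crossf("F31", "Cross-distribution Entropy", "cross_distribution", {"m": 2, "n_bins": 512},
               lambda p, q: xent.cross_distribution_entropy(p.primary, p.reference, q.get("m", 2),
                                                            q.get("n_bins", 512))),
        crossf("F32", "Cross-fuzzy Entropy (m=1)", "cross_fuzzy", {"m": 1, "n_exp": 2.0},
               lambda p, q: xent.cross_fuzzy_entropy(p.primary, p.reference, 1, _r(p, q),
                                                     q.get("n_exp", 2.0))),
        crossf("F33", "Cross-fuzzy Entropy (m=2)", "cross_fuzzy", {"m": 2, "n_exp": 2.0},
               lambda p, q: xent.cross_fuzzy_entropy(p.primary, p.reference, 2, _r(p, q),
                                                     q.get("n_exp", 2.0))),
        crossf("F34", "Cross-Kolmogorov Entropy (m=1)", "cross_kolmogorov", {"m": 1},
               lambda p, q: xent.cross_kolmogorov_entropy(p.primary, p.reference, 1, _r(p, q))),
        crossf("F35", "Cross-Kolmogorov Entropy (m=2)", "cross_kolmogorov", {"m": 2},
               lambda p, q: xent.cross_kolmogorov_entropy(p.primary, p.reference, 2, _r(p, q))),
        crossf("F36", "Cross-sample entropy (m=0)", "cross_sample", {"m": 0},
               lambda p, q: xent.cross_sample_entropy(p.primary, p.reference, 0, _r(p, q))),
        crossf("F37", "Cross-sample entropy (m=1)", "cross_sample", {"m": 1},
               lambda p, q: xent.cross_sample_entropy(p.primary, p.reference, 1, _r(p, q))),
        crossf("F38", "Cross-sample entropy (m=2)", "cross_sample", {"m": 2},
               lambda p, q: xent.cross_sample_entropy(p.primary, p.reference, 2, _r(p, q))),
        crossf("F39", "Cross-spectral Entropy", "cross_spectral", {},
               lambda p, q: xent.cross_spectral_entropy(p.primary, p.reference)),
    ]
    registry = {s.feature_id: s for s in specs}
    assert len(registry) == 39 and tuple(registry) == FEATURE_IDS
    return registry


REGISTRY: dict[str, FeatureSpec] = _build_registry()


def compute_feature(feature_id: str, pair: SamplePair, params: dict | None = None) -> float:
    """Evaluate a single registry feature on a sample pair.

    ``params`` overrides the registry defaults for that feature only.
    """
    if feature_id not in REGISTRY:
        raise RegistryError(f"unknown feature id {feature_id!r}")
    spec = REGISTRY[feature_id]
    merged = dict(spec.params)
    if params:
        merged.update(params)
    try:
        return float(spec.fn(pair, merged))
    except (InsufficientLengthError, InvalidInputError) as exc:
        raise type(exc)(f"{feature_id}: {exc}") from exc


def extract_features(pair: SamplePair, params: dict[str, dict] | None = None) -> FeatureVector:
    """Compute the full ordered F1..F39 vector for one sample pair.

    Non-finite raw values are kept as NaN here and flagged; the table-level
    imputation (training-set column median) happens in
    :func:`build_feature_table` / :func:`impute_feature_table`.
    """
    if pair.primary.size < sent.MIN_SIGNAL_LENGTH:
        raise InsufficientLengthError(
            f"registry minimum is N >= {sent.MIN_SIGNAL_LENGTH}, got {pair.primary.size}"
        )
    values = np.empty(39)
    nonfinite: list[str] = []
    for i, fid in enumerate(FEATURE_IDS):
        v = compute_feature(fid, pair, (params or {}).get(fid))
        if not math.isfinite(v):
            nonfinite.append(fid)
            v = math.nan
        values[i] = v
    return FeatureVector(values, pair.class_label, pair.source_image_id,
                         nonfinite_ids=tuple(nonfinite))


def build_feature_table(pairs: list[SamplePair], params: dict[str, dict] | None = None,
                        impute: bool = True) -> pd.DataFrame:
    """Extract features for many pairs into a tidy table.

    Columns: ``sample_id, class, F1..F39``.  With ``impute=True`` non-finite
    entries are replaced by their column median over the table (the documented
    imputation rule); affected cells are listed in ``df.attrs['imputed']``.
    """
    rows = []
    imputed: list[tuple[str, str]] = []
    for i, pair in enumerate(pairs):
        fv = extract_features(pair, params)
        sample_id = fv.source_image_id or f"sample_{i}"
        row = {"sample_id": f"{sample_id}:{fv.class_label.value}:{i}",
               "class": fv.class_label.value}
        row.update(fv.as_dict())
        for fid in fv.nonfinite_ids:
            imputed.append((row["sample_id"], fid))
        rows.append(row)
    df = pd.DataFrame(rows)
    if impute:
        df = impute_feature_table(df)
    df.attrs["imputed"] = imputed
    return df


def impute_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Replace non-finite feature values by the finite column median (0 if none)."""
    df = df.copy()
    for fid in FEATURE_IDS:
        col = df[fid].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[~bad]
            fill = float(np.median(finite)) if finite.size else 0.0
            col[bad] = fill
            df[fid] = col
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """CSV round-trip exact to 12 significant digits."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["sample_id", "class", *FEATURE_IDS]
    if list(df.columns) != expected:
        raise InvalidInputError("feature table header must be sample_id,class,F1..F39")
    return df
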