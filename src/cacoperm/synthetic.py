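"""Seeded synthetic QSPR data with known ground truth.

Emulates the statistical structure a Caco-2 log Papp descriptor matrix
presents to the pipeline — informative, redundant (|r| > 0.95 with a
source), near-constant and pure-noise columns, missing entries, and a
smooth nonlinear descriptor -> response map with Gaussian noise whose
location and spread match the modelled response distribution (mean -5.34,
range width 3.92 log units by default). It makes no attempt to imitate
real descriptor marginals or chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .druglikeness import PropertyProfile

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_qspr_dataset", "generate_property_table"]

# log Papp response statistics of the modelled 1817-compound permeability set
DEFAULT_RESPONSE_MEAN = -5.34
DEFAULT_RESPONSE_RANGE = (-7.70, -3.78)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic descriptor matrix and response."""

    n_compounds: int = 800
    n_informative: int = 5
    n_redundant: int = 10
    n_noise: int = 85
    n_near_constant: int = 2
    missing_fraction: float = 0.02
    noise_sd: float = 0.4
    response_mean: float = DEFAULT_RESPONSE_MEAN
    response_range: tuple[float, float] = DEFAULT_RESPONSE_RANGE
    seed: int = 0

    def validate(self, with_response: bool = True) -> None:
        counts = (self.n_compounds, self.n_informative, self.n_redundant,
                  self.n_noise, self.n_near_constant)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_compounds == 0:
            raise ValueError("cannot generate a dataset with zero compounds")
        if with_response and self.n_informative < 1:
            raise ValueError("a response requires at least one informative column")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.response_range[0] >= self.response_range[1]:
            raise ValueError("response_range must satisfy min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery tests."""

    informative_columns: list[str]
    redundant_map: dict[str, str]
    true_function: str
    realized_noise_sd: float
    noiseless_response: np.ndarray = field(repr=False, default=None)


# Fixed smooth nonlinear map of the (standard-normal) informative columns:
# linear terms for every column (descriptors typically show a marginal
# correlation with log Papp), plus one pairwise interaction (z4*z5) and one
# non-monotone term (z3^2) so tree/kernel learners can outperform a linear
# fit; roughly a quarter of the signal variance is nonlinear.
_TRUE_FUNCTION_DOC = (
    "1.2*z1 + 1.0*z2 + 0.8*z3 + 0.7*z4 + 0.6*z5 + 0.8*z4*z5 + 0.6*(z3^2 - 1)"
)
_COEF_LINEAR = (1.2, 1.0, 0.8, 0.7, 0.6)


def _true_function(Z: np.ndarray) -> np.ndarray:
    k = Z.shape[1]
    f = np.zeros(Z.shape[0])
    for j in range(k):
        f += _COEF_LINEAR[j % len(_COEF_LINEAR)] * Z[:, j]
    if k >= 5:
        f += 0.8 * Z[:, 3] * Z[:, 4]
    elif k >= 2:
        f += 0.8 * Z[:, 0] * Z[:, 1]
    if k >= 3:
        f += 0.6 * (Z[:, 2] ** 2 - 1.0)
    else:
        f += 0.6 * (Z[:, 0] ** 2 - 1.0)
    return f


def generate_qspr_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate (descriptor matrix, log Papp response, ground truth).

    The noiseless response is an affine rescaling of the fixed nonlinear
    map of the informative columns such that its sample range width equals
    the requested range width and its sample mean equals ``response_mean``
    exactly; Gaussian noise with sd ``noise_sd`` is then added. Redundant
    columns are linear transforms of informative sources plus jitter
    (sd = 0.05 of the source sd, giving pairwise |r| > 0.95). Missing
    entries are placed completely at random in the descriptor matrix only.
    Identical spec (including seed) gives bit-identical output.
    """
    spec.validate(with_response=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds

    Z = rng.standard_normal((n, spec.n_informative))
    inf_names = [f"inf{j + 1}" for j in range(spec.n_informative)]
    columns: dict[str, np.ndarray] = dict(zip(inf_names, Z.T))

    redundant_map: dict[str, str] = {}
    for j in range(spec.n_redundant):
        src = inf_names[j % spec.n_informative]
        name = f"red{j + 1}_{src}"
        source = columns[src]
        a = rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
        b = rng.normal(0, 1)
        jitter = rng.normal(0, 0.05 * source.std(), size=n)
        columns[name] = a * source + b + jitter
        redundant_map[name] = src

    for j in range(spec.n_noise):
        columns[f"noise{j + 1}"] = rng.standard_normal(n)

    for j in range(spec.n_near_constant):
        base = rng.normal(0, 1)
        col = np.full(n, base)
        n_off = max(1, int(np.floor(0.005 * n))) if n > 1 else 0
        if n_off:
            off_rows = rng.choice(n, size=n_off, replace=False)
            col[off_rows] = base + 3.0
        columns[f"const{j + 1}"] = col

    matrix = pd.DataFrame(columns, index=[f"cmpd{i + 1}" for i in range(n)])

    f = _true_function(Z)
    width_req = spec.response_range[1] - spec.response_range[0]
    width_emp = f.max() - f.min()
    scale = width_req / width_emp if width_emp > 0 else 1.0
    noiseless = spec.response_mean + scale * (f - f.mean())
    noise = rng.normal(0, spec.noise_sd, size=n)
    response = pd.Series(noiseless + noise, index=matrix.index, name="log_papp")

    if spec.missing_fraction > 0:
        mask = rng.random(matrix.shape) < spec.missing_fraction
        values = matrix.to_numpy()
        values[mask] = np.nan
        matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)

    truth = SyntheticTruth(
        informative_columns=inf_names,
        redundant_map=redundant_map,
        true_function=_TRUE_FUNCTION_DOC,
        realized_noise_sd=float(np.std(noise, ddof=1)) if n > 1 else 0.0,
        noiseless_response=noiseless,
    )
    return matrix, response, truth


# Property windows. "pass": intersection of all built-in DLS rule intervals,
# so every rule of every rule set is satisfied. "fail": strictly outside
# every rule's admissible interval simultaneously (everything too large).
# "mixed": uniform over ranges straddling each threshold.
_PASS_WINDOWS = {
    "mw": (200.0, 450.0),
    "mlogp": (-0.5, 4.15),
    "hba": (2, 8),
    "hbd": (0, 5),
    "rbn": (1, 8),
    "tpsa": (10.0, 140.0),
    "n_rings": (0, 5),
    "formal_charge": (-2, 2),
    "csp3_ratio": (0.15, 0.8),
    "h_ratio": (0.6, 1.6),
    "no_to_csp3": (0.10, 1.80),
    "unsat_p": (0.10, 0.43),
}
_FAIL_WINDOWS = {
    "mw": (501.0, 900.0),
    "mlogp": (5.5, 9.0),
    "hba": (11, 16),
    "hbd": (6, 10),
    "rbn": (11, 16),
    "tpsa": (141.0, 250.0),
    "n_rings": (6, 9),
    "formal_charge": (3, 4),
    "csp3_ratio": (0.85, 1.0),
    "h_ratio": (1.7, 2.5),
    "no_to_csp3": (1.85, 3.0),
    "unsat_p": (0.46, 0.9),
}
_MIXED_WINDOWS = {
    "mw": (60.0, 700.0),
    "mlogp": (-6.0, 7.0),
    "hba": (0, 13),
    "hbd": (0, 8),
    "rbn": (0, 13),
    "tpsa": (0.0, 200.0),
    "n_rings": (0, 7),
    "formal_charge": (-3, 3),
    "csp3_ratio": (0.0, 1.0),
    "h_ratio": (0.2, 2.0),
    "no_to_csp3": (0.0, 2.5),
    "unsat_p": (0.0, 0.7),
}
_INT_PROPS = {"hba", "hbd", "rbn", "n_rings", "formal_charge"}


def generate_property_table(n: int, scenario: str, seed: Optional[int] = None) -> list[PropertyProfile]:
    """Seeded physicochemical property profiles for rule-set testing.

    scenario 'all_pass': every profile satisfies every built-in DLS rule;
    'all_fail': every profile violates every rule (all violable
    simultaneously by exceeding the upper bounds); 'mixed': properties
    drawn uniformly from ranges straddling each threshold.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    windows = {"all_pass": _PASS_WINDOWS, "all_fail": _FAIL_WINDOWS, "mixed": _MIXED_WINDOWS}
    if scenario not in windows:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(windows)}")
    win = windows[scenario]
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        kwargs = {}
        for prop, (lo, hi) in win.items():
            if prop in _INT_PROPS:
                kwargs[prop] = int(rng.integers(lo, hi + 1))
            else:
                kwargs[prop] = float(rng.uniform(lo, hi))
        profiles.append(PropertyProfile(id=f"prof{i + 1}", **kwargs))
    return profiles


def informative_recovery(selected_columns, truth: SyntheticTruth) -> set[str]:
    """Informative signals represented in a selected column set.

    A planted informative column counts as recovered when the selection
    contains the column itself or one of its redundant duplicates (the
    correlation filter keeps exactly one member of each near-duplicate
    group, and which member survives is not identified).
    """
    recovered = set()
    for col in selected_columns:
        if col in truth.informative_columns:
            recovered.add(col)
        elif col in truth.redundant_map and truth.redundant_map[col] in truth.informative_columns:
            recovered.add(truth.redundant_map[col])
    return recovered


def property_table_to_frame(profiles: list[PropertyProfile]) -> pd.DataFrame:
    """Property profiles as a DataFrame indexed by compound id."""
    rows = []
    for p in profiles:
        d = vars(p).copy()
        rows.append(d)
    frame = pd.DataFrame(rows).set_index("id")
    return frame
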