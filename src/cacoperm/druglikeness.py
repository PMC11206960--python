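"""Drug-likeness scoring and permeability classification.

Each drug-likeness score (DLS) is the fraction of satisfied rules in a named
rule set; seven rule sets (DLS_01..DLS_07) are built in, and their arithmetic
mean is reported as the consensus score DLS_cons. Predicted log Papp values
(log10 cm/s) are binned into high / medium / low apparent-permeability
classes at -5 and -6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "PropertyProfile",
    "Rule",
    "RuleSet",
    "DLSResult",
    "builtin_rulesets",
    "dls_score",
    "dls_all",
    "ro5_compliant",
    "veber_compliant",
    "classify_permeability",
    "summarize_classes",
]


@dataclass
class PropertyProfile:
    """Physicochemical properties of one compound.

    Parameters
    ----------
    mw : molecular weight, g/mol.
    mlogp : Moriguchi octanol-water partition coefficient.
    hba, hbd : hydrogen-bond acceptor / donor counts.
    rbn : rotatable-bond number.
    tpsa : topological polar surface area, A^2.
    n_rings : ring count.
    formal_charge : net formal charge.
    csp3_ratio : C_sp3 atoms / non-halogen atoms.
    h_ratio : hydrogen atoms / non-halogen atoms.
    no_to_csp3 : (N + O) atoms / C_sp3 atoms; ``None`` when C_sp3 = 0
        (undefined; any rule referencing it then counts as violated).
    unsat_p : molecular-unsaturation ratio (supplied by the property
        provider; no formula is imposed here).
    """

    mw: float
    mlogp: float
    hba: int
    hbd: int
    rbn: int
    tpsa: float
    n_rings: int = 0
    formal_charge: int = 0
    csp3_ratio: float = 0.0
    h_ratio: float = 0.0
    no_to_csp3: Optional[float] = None
    unsat_p: float = 0.0
    id: str = ""


@dataclass(frozen=True)
class Rule:
    """Inclusive interval constraint on one property; ``None`` = unbounded."""

    prop: str
    lower: Optional[float] = None
    upper: Optional[float] = None

    def satisfied_by(self, profile: PropertyProfile) -> bool:
        value = getattr(profile, self.prop)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False  # undefined property -> rule violated
        if self.lower is not None and value < self.lower:
            return False
        if self.upper is not None and value > self.upper:
            return False
        return True


@dataclass(frozen=True)
class RuleSet:
    name: str
    rules: tuple[Rule, ...]

    @property
    def t_rules(self) -> int:
        return len(self.rules)


@dataclass
class DLSResult:
    scores: dict[str, float] = field(default_factory=dict)
    consensus: float = float("nan")


def builtin_rulesets() -> list[RuleSet]:
    """The seven built-in drug-likeness rule sets.

    DLS_01 is the modified rule-of-five form using MlogP <= 4.15 (not
    ClogP <= 5), matching the property set this pipeline computes. All
    bounds are inclusive.
    """
    return [
        RuleSet("DLS_01", (
            Rule("mw", None, 500),
            Rule("mlogp", None, 4.15),
            Rule("hbd", None, 5),
            Rule("hba", None, 10),
        )),
        RuleSet("DLS_02", (
            Rule("hbd", None, 5),
            Rule("hba", 1, 8),
            Rule("mw", 200, 450),
            Rule("mlogp", -2.0, 4.5),
            Rule("rbn", 1, 9),
            Rule("n_rings", None, 5),
        )),
        RuleSet("DLS_03", (
            Rule("hbd", None, 5),
            Rule("hba", None, 10),
            Rule("mw", 200, 500),
            Rule("mlogp", -5.0, 5.0),
            Rule("rbn", None, 8),
            Rule("formal_charge", -2, 2),
        )),
        RuleSet("DLS_04", (
            Rule("hbd", None, 5),
            Rule("hba", 2, 10),
            Rule("mw", 78, 500),
            Rule("mlogp", -0.5, 5.0),
            Rule("csp3_ratio", 0.15, 0.8),
            Rule("h_ratio", 0.6, 1.6),
            Rule("unsat_p", 0.10, 0.45),
        )),
        RuleSet("DLS_05", (
            Rule("no_to_csp3", 0.10, 1.80),
            Rule("unsat_p", None, 0.43),
        )),
        RuleSet("DLS_06", (
            Rule("hbd", None, 5),
            Rule("hba", None, 10),
            Rule("mw", None, 500),
            Rule("mlogp", None, 5),
            Rule("rbn", None, 10),
            Rule("tpsa", None, 140),
        )),
        RuleSet("DLS_07", (
            Rule("rbn", None, 10),
            Rule("tpsa", None, 140),
        )),
    ]


def dls_score(profile: PropertyProfile, ruleset: RuleSet) -> float:
    """Fraction of the rule set's rules satisfied by the profile (nRules/tRules)."""
    if not ruleset.rules:
        raise ValueError(f"rule set {ruleset.name!r} has no rules")
    for rule in ruleset.rules:
        if not hasattr(profile, rule.prop):
            raise AttributeError(f"profile lacks property {rule.prop!r} required by {ruleset.name}")
    n_ok = sum(rule.satisfied_by(profile) for rule in ruleset.rules)
    return n_ok / ruleset.t_rules


def dls_all(profile: PropertyProfile, rulesets: Optional[Sequence[RuleSet]] = None) -> DLSResult:
    """All seven DLS scores plus their mean (the consensus, DLS_cons)."""
    rulesets = list(rulesets) if rulesets is not None else builtin_rulesets()
    scores = {rs.name: dls_score(profile, rs) for rs in rulesets}
    consensus = sum(scores.values()) / len(scores)
    return DLSResult(scores=scores, consensus=consensus)


_RO5_RULES = (
    Rule("mw", None, 500),
    Rule("mlogp", None, 4.15),
    Rule("hbd", None, 5),
    Rule("hba", None, 10),
)

_VEBER_RULES = (
    Rule("rbn", None, 10),
    Rule("tpsa", None, 140),
)


def _check_rules(profile: PropertyProfile, rules: Iterable[Rule]) -> tuple[bool, list[str]]:
    violated = [r.prop for r in rules if not r.satisfied_by(profile)]
    return (len(violated) == 0, violated)


def ro5_compliant(profile: PropertyProfile) -> tuple[bool, list[str]]:
    """Lipinski rule-of-five compliance (MlogP form); bounds inclusive.

    Compliant means zero violations of {MW <= 500, MlogP <= 4.15,
    HBD <= 5, HBA <= 10}; the second element lists violated properties.
    """
    return _check_rules(profile, _RO5_RULES)


def veber_compliant(profile: PropertyProfile) -> tuple[bool, list[str]]:
    """Veber compliance: RBN <= 10 and TPSA <= 140 A^2."""
    return _check_rules(profile, _VEBER_RULES)


def classify_permeability(log_papp: float) -> str:
    """Bin a log Papp value (log10 cm/s) into 'high' / 'medium' / 'low'.

    high: log Papp > -5; medium: -6 <= log Papp <= -5; low: log Papp < -6.
    Boundary values -5 and -6 are medium.
    """
    if not math.isfinite(log_papp):
        raise ValueError(f"log Papp must be finite, got {log_papp!r}")
    if log_papp > -5.0:
        return "high"
    if log_papp >= -6.0:
        return "medium"
    return "low"


def summarize_classes(values: Sequence[float]) -> dict[str, dict[str, float]]:
    """Counts and percentages (1 decimal place) per permeability class."""
    values = list(values)
    if not values:
        raise ValueError("summarize_classes requires at least one value")
    counts = {"high": 0, "medium": 0, "low": 0}
    for v in values:
        counts[classify_permeability(v)] += 1
    n = len(values)
    return {
        label: {"count": c, "percent": round(100.0 * c / n, 1)}
        for label, c in counts.items()
    }
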