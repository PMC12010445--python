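"""Scenario configuration: generative parameters plus deployment context.

A scenario bundles the generative model parameters with the two pieces
of context the math itself never touches: which constant treatment rule
was in force historically, and whether Y = 1 is a desirable outcome
(e.g. 6-month survival) or an undesirable one (e.g. a heart attack).
Polarity only flips the direction of the harm inequalities downstream;
it never changes probabilities, scores or AUC.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .model import OutcomeModelParams
from .policy import Policy, constant_policy

__all__ = ["Polarity", "ScenarioConfig"]


class Polarity(str, enum.Enum):
    """Whether Y = 1 is a good outcome for the patient."""

    DESIRABLE = "desirable"
    UNDESIRABLE = "undesirable"

    @property
    def flipped(self) -> "Polarity":
        return Polarity.UNDESIRABLE if self is Polarity.DESIRABLE else Polarity.DESIRABLE


# exact key set of the on-disk scenario format
_KEYS = ("beta0", "beta_x", "beta_t", "beta_xt", "p_x", "historical_policy", "polarity")


@dataclass(frozen=True)
class ScenarioConfig:
    params: OutcomeModelParams
    historical_policy: int
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.historical_policy not in (0, 1):
            raise InvalidParameterError(
                f"historical_policy must be 0 or 1, got {self.historical_policy!r}"
            )

    @property
    def pi0(self) -> Policy:
        """The constant historical policy as a Policy object."""
        return constant_policy(self.historical_policy)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "beta0": p.beta0,
            "beta_x": p.beta_x,
            "beta_t": p.beta_t,
            "beta_xt": p.beta_xt,
            "p_x": p.p_x,
            "historical_policy": self.historical_policy,
            "polarity": self.polarity.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        missing = [k for k in _KEYS if k not in d]
        if missing:
            raise InvalidParameterError(f"scenario file missing keys: {missing}")
        unknown = [k for k in d if k not in _KEYS]
        if unknown:
            raise InvalidParameterError(f"scenario file has unknown keys: {unknown}")
        return cls(
            params=OutcomeModelParams(
                beta0=float(d["beta0"]),
                beta_x=float(d["beta_x"]),
                beta_t=float(d["beta_t"]),
                beta_xt=float(d["beta_xt"]),
                p_x=float(d["p_x"]),
            ),
            historical_policy=int(d["historical_policy"]),
            polarity=Polarity(d["polarity"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
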