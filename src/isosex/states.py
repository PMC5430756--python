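"""Tip character states: heterogametic type per species, with coding schemes.

Two codings of the same data are used when counting transitions:

* ``two_state`` — XY vs ZW only; species whose system is distinct-but-
  uncharacterized (coded OTHER upstream, e.g. the all-male-brood species
  *Armadillidium assimile*) are folded into UNKNOWN;
* ``three_state`` — XY, ZW and OTHER as a third reachable state.

UNKNOWN tips carry no information (zero parsimony cost / all-ones partial
likelihoods in every state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

__all__ = ["CharacterStates", "STATE_VALUES", "read_states_tsv", "write_states_tsv"]

STATE_VALUES = ("XY", "ZW", "OTHER", "UNKNOWN")
Scheme = Literal["two_state", "three_state"]


@dataclass(frozen=True)
class CharacterStates:
    """Species -> heterogametic type map under a fixed coding scheme."""

    scheme: Scheme
    states: Mapping[str, str]

    def __post_init__(self):
        if self.scheme not in ("two_state", "three_state"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        cleaned = {}
        for name, s in self.states.items():
            s = s.upper()
            if s not in STATE_VALUES:
                raise ValueError(f"invalid state {s!r} for {name!r}")
            if self.scheme == "two_state" and s == "OTHER":
                s = "UNKNOWN"
            cleaned[name] = s
        object.__setattr__(self, "states", cleaned)

    @property
    def state_space(self) -> tuple[str, ...]:
        """Observable states under the scheme (UNKNOWN is missing data)."""
        return ("XY", "ZW") if self.scheme == "two_state" else ("XY", "ZW", "OTHER")

    def for_tips(self, labels: list[str]) -> dict[str, str]:
        """States aligned to a tree's tips; absent tips become UNKNOWN (warned)."""
        missing = [l for l in labels if l not in self.states]
        if missing:
            warnings.warn(
                f"{len(missing)} tree tip(s) absent from the state table treated "
                f"as UNKNOWN: {missing}",
                stacklevel=2,
            )
        return {l: self.states.get(l, "UNKNOWN") for l in labels}

    def observed(self) -> dict[str, str]:
        return {k: v for k, v in self.states.items() if v != "UNKNOWN"}

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATE_VALUES}
        for s in self.states.values():
            out[s] += 1
        return out


def read_states_tsv(path, scheme: Scheme = "three_state") -> CharacterStates:
    """Read a two-column TSV ``species<TAB>state`` (states XY/ZW/OTHER/UNKNOWN)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species", "state"):
        if col not in df.columns:
            raise ValueError(f"state table missing column {col!r}")
    return CharacterStates(scheme, dict(zip(df["species"], df["state"])))


def write_states_tsv(states: CharacterStates, path) -> None:
    pd.DataFrame(
        sorted(states.states.items()), columns=["species", "state"]
    ).to_csv(path, sep="\t", index=False)
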