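"""Shared container for transition counts on a tree."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TransitionSummary:
    """Total and per-direction transition counts.

    ``total`` is the minimum count (parsimony) or the expected count
    (stochastic mapping, averaged over maps); ``by_direction`` maps
    (from_state, to_state) pairs to counts and sums to ``total``.
    ``n_maps`` is 0 for parsimony results.
    """

    total: float
    by_direction: dict[tuple[str, str], float] = field(default_factory=dict)
    n_maps: int = 0

    def __post_init__(self):
        if self.by_direction:
            s = sum(self.by_direction.values())
            if abs(s - self.total) > 1e-9:
                raise ValueError(
                    f"direction counts sum to {s}, expected total {self.total}"
                )
        if any(v < 0 for v in self.by_direction.values()):
            raise ValueError("negative direction count")

    def count(self, from_state: str, to_state: str) -> float:
        return self.by_direction.get((from_state, to_state), 0.0)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "n_maps": self.n_maps,
            "by_direction": {
                f"{a}->{b}": v for (a, b), v in sorted(self.by_direction.items())
            },
        }
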