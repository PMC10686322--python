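"""Single-site binding free energy between two tripeptide windows.

Each interaction unit is a window of three consecutive residue states.  The
window hydropathy is the arithmetic mean of the three water->octanol transfer
free energies, and the window's electron-density sign is the sign of the
magnitude-weighted sum of the per-state signs.  A pair of windows is scored
by three regimes:

* both window means negative (both hydrophobic): the energies add,
  ``dg = -(|ma| + |mb|)`` - burying two hydrophobic patches against each
  other is better than leaving either wet.
* exactly one mean negative (hydrophobic against polar): the unbalanced
  polar density is better served by water, ``dg = +min(|ma|, |mb|)``.
* both means non-negative (both polar): complementary electron density
  (opposite window signs) attracts, ``dg = -min(|ma|, |mb|)``; matching
  signs repel, ``dg = |ma| + |mb|``.

Energies below ``-kT`` (0.693 kcal/mol at 25 degC) are classified as stable
(rarely reversible); favorable energies above ``-kT`` are marginal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ColbindError
from .scale import KT_REF, ResidueState

__all__ = [
    "TripeptideWindow",
    "InteractionResult",
    "make_window",
    "window_sign",
    "single_site_dG",
    "classify_stability",
    "REGIMES",
]

REGIMES = (
    "both_hydrophobic_additive",
    "mixed_sign_penalty",
    "opposite_electroneg_attraction",
    "same_electroneg_repulsion",
)


@dataclass(frozen=True)
class TripeptideWindow:
    """Three consecutive residue states from one parent sequence.

    ``start`` is the 1-based index of the first residue in the parent;
    ``source`` marks which side of the pairing the window came from.
    """

    source: str
    start: int
    states: tuple[ResidueState, ResidueState, ResidueState]

    def __post_init__(self) -> None:
        if len(self.states) != 3:
            raise ColbindError("a tripeptide window needs exactly 3 states")

    @property
    def mean_hydropathy(self) -> float:
        """Mean water->octanol transfer free energy, kcal/mol."""
        return sum(s.dg_woct for s in self.states) / 3.0

    @property
    def electroneg_sign(self) -> int:
        return window_sign(self)

    @property
    def labels(self) -> tuple[str, str, str]:
        return tuple(s.state_label for s in self.states)  # type: ignore[return-value]


@dataclass(frozen=True)
class InteractionResult:
    """Scored pairing of two windows: energy, regime and stability class."""

    dg: float
    regime: str
    stability: str


def make_window(
    states: Sequence[ResidueState], start: int = 1, source: str = "peptide"
) -> TripeptideWindow:
    """Build the tripeptide window starting at 1-based ``start``.

    ``states`` is the full residue-state list of the parent sequence (or just
    the three states of interest with ``start=1``).
    """
    if len(states) < 3:
        raise ColbindError("sequence too short for a tripeptide window")
    if start < 1 or start + 2 > len(states):
        raise ColbindError(
            f"window start {start} out of range for length {len(states)}"
        )
    triple = tuple(states[start - 1 : start + 2])
    return TripeptideWindow(source=source, start=start, states=triple)  # type: ignore[arg-type]


def window_sign(window: TripeptideWindow) -> int:
    """Electron-density sign of a window.

    Sign of the sum of per-state electronegativity signs weighted by the
    magnitude of their transfer free energies, so a strongly charged state
    (e.g. E-, |dg| = 3.63) dominates a weaker opposite one (R+, 1.81).
    """
    total = sum(s.electroneg * abs(s.dg_woct) for s in window.states)
    if total > 0:
        return 1
    if total < 0:
        return -1
    return 0


def single_site_dG(
    a: TripeptideWindow,
    b: TripeptideWindow,
    kt: float = KT_REF,
    attraction_spread_term: bool = False,
) -> InteractionResult:
    """Score one window pairing under the three-regime rules.

    Symmetric in its arguments.  ``attraction_spread_term`` adds
    ``max(ma, mb) - min(ma, mb)`` to the attraction branch; this alternate
    form is retained for investigation only and is not used by default (it
    breaks the observed near-equality of the charge-complementary and
    hydrophobic LRR-10 sites).
    """
    ma, mb = a.mean_hydropathy, b.mean_hydropathy
    if ma < 0 and mb < 0:
        dg = -(abs(ma) + abs(mb))
        regime = "both_hydrophobic_additive"
    elif (ma < 0) != (mb < 0):
        dg = min(abs(ma), abs(mb))
        regime = "mixed_sign_penalty"
    else:
        if window_sign(a) * window_sign(b) < 0:
            dg = -min(abs(ma), abs(mb))
            if attraction_spread_term:
                dg += max(ma, mb) - min(ma, mb)
            regime = "opposite_electroneg_attraction"
        else:
            dg = abs(ma) + abs(mb)
            regime = "same_electroneg_repulsion"
    return InteractionResult(dg=dg, regime=regime, stability=classify_stability(dg, kt))


def classify_stability(dg: float, kt: float = KT_REF) -> str:
    """Classify an energy against the thermal fluctuation scale.

    ``dg < -kt`` -> ``"stable"`` (rarely reversible); ``-kt <= dg < 0`` ->
    ``"marginal"`` (favorable but likely reversible); ``dg >= 0`` ->
    ``"unfavorable"``.
    """
    if kt <= 0:
        raise ColbindError(f"kt must be positive, got {kt}")
    if dg < -kt:
        return "stable"
    if dg < 0:
        return "marginal"
    return "unfavorable"
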