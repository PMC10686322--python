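"""Wimley-White octanol hydropathy scale with explicit side-chain charge states.

The scale stores, for every canonical amino acid and every charge state it can
adopt between pH 2 and pH 9, the experimental free energy of transferring the
side chain from water to n-octanol (``dg_woct``, kcal/mol; negative values are
hydrophobic).  Ionizable residues carry separate entries for their neutral and
charged forms (e.g. ``H0`` vs ``H+``), which is what makes the downstream
binding-energy screen pH-aware: a :class:`ProtonationPolicy` selects which
states are populated at each supported pH.

The thermal-energy reference kT = 0.693 kcal/mol at 25 degC sets the stability
threshold used by the screen; it scales linearly with absolute temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ColbindError

__all__ = [
    "ResidueState",
    "HydropathyScale",
    "ProtonationPolicy",
    "ThermalModel",
    "load_default_scale",
    "default_policy",
    "states_at_ph",
    "kT",
    "KT_REF",
    "T_REF_K",
    "CANONICAL_RESIDUES",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: kT at the 25 degC reference, kcal/mol.
KT_REF = 0.693
#: Reference absolute temperature, kelvin (25 degC).
T_REF_K = 298.15
ABSOLUTE_ZERO_C = -273.15


@dataclass(frozen=True)
class ResidueState:
    """One amino acid in a specific side-chain charge state.

    Attributes
    ----------
    residue : str
        One-letter amino-acid code.
    state_label : str
        Charge-state label (``"H0"``, ``"H+"``, ``"D-"`` ... or the bare
        letter for non-ionizable residues).
    dg_woct : float
        Water -> octanol side-chain transfer free energy, kcal/mol.
        Negative = hydrophobic.
    electroneg : int
        Electron-density sign: -1 electron-rich (acidic/amide/hydroxyl),
        +1 electron-poor (basic/charged-positive, small low-density),
        0 apolar.
    """

    residue: str
    state_label: str
    dg_woct: float
    electroneg: int


# Water -> octanol side-chain transfer free energies (kcal/mol) with distinct
# charge states for the ionizable side chains.
_OCTANOL_DG: dict[str, tuple[str, float]] = {
    "A": ("A", 0.50),
    "R+": ("R", 1.81),
    "N": ("N", 0.85),
    "D0": ("D", 0.43),
    "D-": ("D", 3.64),
    "C": ("C", -0.02),
    "E0": ("E", 0.11),
    "E-": ("E", 3.63),
    "Q": ("Q", 0.77),
    "G": ("G", 1.15),
    "H0": ("H", 0.11),
    "H+": ("H", 2.33),
    "I": ("I", -1.12),
    "L": ("L", -1.25),
    "K+": ("K", 2.80),
    "M": ("M", -0.67),
    "F": ("F", -1.71),
    "P": ("P", 0.14),
    "S": ("S", 0.46),
    "T": ("T", 0.25),
    "W": ("W", -2.09),
    "Y": ("Y", -0.71),
    "V": ("V", -0.46),
}

# Electron-density sign per state.  Basic / charged-positive side chains and
# the small low-electron-density residues (G, P, A) are electron-poor (+1);
# acidic, amide and hydroxyl side chains are electron-rich (-1); the large
# aliphatic/aromatic/thioether side chains are apolar (0).
_ELECTRONEG: dict[str, int] = {
    "K+": +1, "R+": +1, "H+": +1, "G": +1, "P": +1, "A": +1,
    "D-": -1, "E-": -1, "D0": -1, "E0": -1,
    "N": -1, "Q": -1, "S": -1, "T": -1, "Y": -1, "H0": -1,
    "L": 0, "I": 0, "V": 0, "F": 0, "M": 0, "W": 0, "C": 0,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A named table of :class:`ResidueState` entries keyed by state label."""

    name: str
    states: dict[str, ResidueState]

    def state(self, label: str) -> ResidueState:
        try:
            return self.states[label]
        except KeyError:
            raise ColbindError(f"unknown state label {label!r}") from None

    def states_of(self, residue: str) -> list[ResidueState]:
        """All charge states shipped for a one-letter residue code."""
        found = [s for s in self.states.values() if s.residue == residue]
        if not found:
            raise ColbindError(f"unknown residue {residue!r}")
        return found

    def with_overrides(
        self,
        dg: dict[str, float] | None = None,
        electroneg: dict[str, int] | None = None,
        name: str | None = None,
    ) -> "HydropathyScale":
        """Return a copy with selected dg_woct / electroneg values replaced."""
        states = dict(self.states)
        for label, value in (dg or {}).items():
            states[label] = replace(self.state(label), dg_woct=float(value))
        for label, sign in (electroneg or {}).items():
            if sign not in (-1, 0, 1):
                raise ColbindError(f"electroneg sign must be -1, 0 or 1, got {sign!r}")
            states[label] = replace(
                states.get(label, self.state(label)), electroneg=int(sign)
            )
        return HydropathyScale(name=name or self.name, states=states)


def load_default_scale() -> HydropathyScale:
    """The embedded Wimley-White octanol scale with charge-state entries."""
    states = {
        label: ResidueState(residue, label, dg, _ELECTRONEG[label])
        for label, (residue, dg) in _OCTANOL_DG.items()
    }
    return HydropathyScale(name="wimley-white-octanol", states=states)


def _step_table(acidic_dual_ph4: bool) -> dict[tuple[str, float], tuple[str, ...]]:
    table: dict[tuple[str, float], tuple[str, ...]] = {}
    for ph in (2.0, 4.0, 7.0, 9.0):
        for res in CANONICAL_RESIDUES:
            if res == "D":
                if ph == 2.0:
                    labels: tuple[str, ...] = ("D0",)
                elif ph == 4.0 and acidic_dual_ph4:
                    labels = ("D-", "D0")
                else:
                    labels = ("D-",)
            elif res == "E":
                if ph == 2.0:
                    labels = ("E0",)
                elif ph == 4.0 and acidic_dual_ph4:
                    labels = ("E-", "E0")
                else:
                    labels = ("E-",)
            elif res == "H":
                if ph in (2.0, 4.0):
                    labels = ("H+",)
                elif ph == 7.0:
                    labels = ("H0", "H+")
                else:
                    labels = ("H0",)
            elif res == "K":
                labels = ("K+",)
            elif res == "R":
                labels = ("R+",)
            else:
                labels = (res,)
            table[(res, ph)] = labels
    return table


@dataclass(frozen=True)
class ProtonationPolicy:
    """Step table mapping (residue, pH) to the allowed charge-state labels.

    Only the four pH conditions 2, 4, 7 and 9 are supported; intermediate
    values are rejected rather than interpolated.  At pH 2 the acidic side
    chains are neutral only (D0, E0); from pH 4 upward they are charged.
    Histidine is protonated at pH 2 and 4, both H0 and H+ are enumerated at
    pH 7, and only H0 survives at pH 9.  Lysine and arginine stay charged
    across the whole supported range (side-chain pKa > 9).
    """

    supported_ph: tuple[float, ...] = (2.0, 4.0, 7.0, 9.0)
    table: dict[tuple[str, float], tuple[str, ...]] = field(
        default_factory=lambda: _step_table(acidic_dual_ph4=False)
    )

    def allowed_labels(self, residue: str, ph: float) -> tuple[str, ...]:
        residue = residue.upper()
        if residue not in CANONICAL_RESIDUES:
            raise ColbindError(f"unknown residue {residue!r}")
        ph = float(ph)
        if ph not in self.supported_ph:
            supported = ", ".join(str(p) for p in self.supported_ph)
            raise ColbindError(
                f"unsupported pH {ph}; supported values are {supported}"
            )
        return self.table[(residue, ph)]

    def with_override(
        self, residue: str, ph: float, labels: tuple[str, ...]
    ) -> "ProtonationPolicy":
        if not labels:
            raise ColbindError("a policy override must allow at least one state")
        table = dict(self.table)
        table[(residue.upper(), float(ph))] = tuple(labels)
        return ProtonationPolicy(supported_ph=self.supported_ph, table=table)


def default_policy(acidic_dual_ph4: bool = False) -> ProtonationPolicy:
    """The shipped pH policy.

    ``acidic_dual_ph4=True`` enumerates both D0/D- and E0/E- at pH 4 instead
    of the charged-only default.
    """
    return ProtonationPolicy(table=_step_table(acidic_dual_ph4))


def states_at_ph(
    residue: str,
    ph: float,
    scale: HydropathyScale | None = None,
    policy: ProtonationPolicy | None = None,
) -> list[ResidueState]:
    """Allowed :class:`ResidueState` set for a residue at a supported pH."""
    scale = scale or load_default_scale()
    policy = policy or default_policy()
    return [scale.state(label) for label in policy.allowed_labels(residue, ph)]


@dataclass(frozen=True)
class ThermalModel:
    """Thermal energy kT, anchored at 0.693 kcal/mol for 25 degC."""

    kt_ref: float = KT_REF
    t_ref: float = T_REF_K

    def kt(self, temperature_celsius: float = 25.0) -> float:
        t_kelvin = temperature_celsius - ABSOLUTE_ZERO_C
        if t_kelvin <= 0:
            raise ColbindError(
                f"non-physical temperature {temperature_celsius} degC"
            )
        return self.kt_ref * (t_kelvin / self.t_ref)


def kT(temperature_celsius: float = 25.0, kt_ref: float = KT_REF) -> float:
    """Thermal energy in kcal/mol at the given temperature in Celsius."""
    return ThermalModel(kt_ref=kt_ref).kt(temperature_celsius)
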