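"""Exhaustive tripeptide-window scan of a peptide against a target protein.

For a peptide of length m and a target of length n there are (m-2) x (n-2)
overlapping window pairs (step 1 on both sequences).  Within each window the
allowed protonation states at the requested pH combine as a full Cartesian
product, so a window holding two histidines contributes four state
combinations at pH 7.  Every (peptide window, target window, state
combination) triple is scored with the single-site model and collected into a
:class:`ScanTable`; per-target-position minima give the binding profile the
figures of a whole-chain scan would plot.

Higher-level utilities compare peptides across pH values, apply linear
surface-accessibility weights, and search single-edit peptide variants for
pH-robust binders (the route by which TKKTLRT + one leucine insertion yields
the pH-independent TKKLTLRT binder).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import pandas as pd

from .errors import ColbindError
from .interaction import (
    InteractionResult,
    TripeptideWindow,
    classify_stability,
    single_site_dG,
)
from .scale import (
    CANONICAL_RESIDUES,
    KT_REF,
    HydropathyScale,
    ProtonationPolicy,
    default_policy,
    load_default_scale,
)

__all__ = [
    "InteractionSite",
    "ScanTable",
    "DesignCandidate",
    "scan_pair",
    "multi_ph_scan",
    "compare_peptides",
    "apply_accessibility",
    "design_variants",
]

TSV_COLUMNS = [
    "peptide_id",
    "pep_start",
    "pep_states",
    "target_id",
    "target_start",
    "target_states",
    "ph",
    "dg_kcal_mol",
    "dg_full",
    "regime",
    "stability",
]


@dataclass(frozen=True)
class InteractionSite:
    """One scored peptide-window x target-window pairing at a given pH."""

    peptide_id: str
    pep_start: int
    pep_window_states: tuple[str, str, str]
    target_id: str
    target_start: int
    target_window_states: tuple[str, str, str]
    ph: float
    result: InteractionResult


@dataclass
class ScanTable:
    """All interaction sites for one peptide/target/pH combination."""

    sites: list[InteractionSite]
    per_position_min: dict[int, float]
    parameters: dict

    def min_dg(self) -> float:
        """Best (lowest) energy over all sites."""
        if not self.sites:
            raise ColbindError("empty scan table has no minimum")
        return min(s.result.dg for s in self.sites)

    def count_below(self, threshold: float) -> int:
        return sum(1 for s in self.sites if s.result.dg < threshold)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "peptide_id": s.peptide_id,
                "pep_start": s.pep_start,
                "pep_states": ",".join(s.pep_window_states),
                "target_id": s.target_id,
                "target_start": s.target_start,
                "target_states": ",".join(s.target_window_states),
                "ph": s.ph,
                "dg_kcal_mol": f"{s.result.dg:.3f}",
                "dg_full": repr(s.result.dg),
                "regime": s.result.regime,
                "stability": s.result.stability,
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScanTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sites = []
        for row in df.itertuples(index=False):
            dg = float(row.dg_full)
            sites.append(
                InteractionSite(
                    peptide_id=row.peptide_id,
                    pep_start=int(row.pep_start),
                    pep_window_states=tuple(row.pep_states.split(",")),  # type: ignore[arg-type]
                    target_id=row.target_id,
                    target_start=int(row.target_start),
                    target_window_states=tuple(row.target_states.split(",")),  # type: ignore[arg-type]
                    ph=float(row.ph),
                    result=InteractionResult(
                        dg=dg, regime=row.regime, stability=row.stability
                    ),
                )
            )
        return cls(
            sites=sites,
            per_position_min=_position_minima(sites),
            parameters={"ph": sites[0].ph if sites else None},
        )


@dataclass(frozen=True)
class DesignCandidate:
    """A single-edit peptide variant with its pH-robustness score.

    ``robustness`` is the worst case over the pH set of the best (minimum)
    site energy against the target - a minimax criterion: low robustness
    means the candidate keeps a strong site at every pH considered.
    """

    sequence: str
    edit: str
    robustness: float


def _validate_protein(sequence: str, what: str) -> str:
    sequence = sequence.strip().upper()
    if len(sequence) < 3:
        raise ColbindError(f"{what} sequence too short (need >= 3 residues)")
    for i, letter in enumerate(sequence, start=1):
        if letter not in CANONICAL_RESIDUES:
            raise ColbindError(
                f"non-canonical residue {letter!r} at position {i} of {what}"
            )
    return sequence


def _window_state_combos(
    sequence: str,
    ph: float,
    scale: HydropathyScale,
    policy: ProtonationPolicy,
    source: str,
) -> list[tuple[int, list[TripeptideWindow]]]:
    """Per window start, every protonation-state combination as a window.

    Combinations are emitted in lexicographic state-label order.
    """
    per_residue = [
        sorted(policy.allowed_labels(res, ph)) for res in sequence
    ]
    out = []
    for start in range(1, len(sequence) - 1):
        combos = []
        for labels in itertools.product(*per_residue[start - 1 : start + 2]):
            states = tuple(scale.state(lab) for lab in labels)
            combos.append(TripeptideWindow(source=source, start=start, states=states))  # type: ignore[arg-type]
        out.append((start, combos))
    return out


def _position_minima(sites: list[InteractionSite]) -> dict[int, float]:
    minima: dict[int, float] = {}
    for s in sites:
        p = s.target_start
        if p not in minima or s.result.dg < minima[p]:
            minima[p] = s.result.dg
    return dict(sorted(minima.items()))


def scan_pair(
    peptide: str,
    target: str,
    ph: float,
    scale: HydropathyScale | None = None,
    policy: ProtonationPolicy | None = None,
    kt: float = KT_REF,
    peptide_id: str = "peptide",
    target_id: str = "target",
) -> ScanTable:
    """Score every window pair and state combination at one pH.

    Sites are ordered by ascending target start, then peptide start, then
    lexicographic state labels, so serialized output is bit-stable.
    """
    scale = scale or load_default_scale()
    policy = policy or default_policy()
    peptide = _validate_protein(peptide, "peptide")
    target = _validate_protein(target, "target")

    pep_windows = _window_state_combos(peptide, ph, scale, policy, "peptide")
    tgt_windows = _window_state_combos(target, ph, scale, policy, "target")

    sites: list[InteractionSite] = []
    for tgt_start, tgt_combos in tgt_windows:
        for pep_start, pep_combos in pep_windows:
            for pw in pep_combos:
                for tw in tgt_combos:
                    res = single_site_dG(pw, tw, kt=kt)
                    sites.append(
                        InteractionSite(
                            peptide_id=peptide_id,
                            pep_start=pep_start,
                            pep_window_states=pw.labels,
                            target_id=target_id,
                            target_start=tgt_start,
                            target_window_states=tw.labels,
                            ph=float(ph),
                            result=res,
                        )
                    )
    return ScanTable(
        sites=sites,
        per_position_min=_position_minima(sites),
        parameters={
            "peptide_id": peptide_id,
            "target_id": target_id,
            "ph": float(ph),
            "kt": kt,
            "scale": scale.name,
        },
    )


def multi_ph_scan(
    peptide: str,
    target: str,
    ph_list,
    scale: HydropathyScale | None = None,
    policy: ProtonationPolicy | None = None,
    kt: float = KT_REF,
    peptide_id: str = "peptide",
    target_id: str = "target",
) -> dict[float, ScanTable]:
    """One :func:`scan_pair` table per pH; window geometry is shared."""
    return {
        float(ph): scan_pair(
            peptide, target, ph,
            scale=scale, policy=policy, kt=kt,
            peptide_id=peptide_id, target_id=target_id,
        )
        for ph in ph_list
    }


def compare_peptides(
    peptides,
    target: str,
    ph_list,
    scale: HydropathyScale | None = None,
    policy: ProtonationPolicy | None = None,
    kt: float = KT_REF,
    target_id: str = "target",
) -> pd.DataFrame:
    """Per (peptide, pH): minimum dg and counts of sites below -kT and -2kT.

    ``peptides`` is a list of sequences or of ``(id, sequence)`` pairs.
    """
    if not peptides:
        raise ColbindError("need at least one peptide")
    named = [
        p if isinstance(p, tuple) else (p, p) for p in peptides
    ]
    rows = []
    for pid, seq in named:
        for ph in ph_list:
            table = scan_pair(
                seq, target, ph,
                scale=scale, policy=policy, kt=kt,
                peptide_id=pid, target_id=target_id,
            )
            rows.append(
                {
                    "peptide_id": pid,
                    "sequence": seq,
                    "ph": float(ph),
                    "min_dg": table.min_dg(),
                    "n_stable": table.count_below(-kt),
                    "n_very_stable": table.count_below(-2 * kt),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["peptide_id", "sequence", "ph", "min_dg", "n_stable", "n_very_stable"],
    )


def apply_accessibility(table: ScanTable, weights: dict[int, float]) -> ScanTable:
    """Scale each site's energy by mean target-window accessibility.

    ``weights`` maps 1-based target positions to values in [0, 1]; buried
    residues (weight 0) pull their sites' energies to zero.  Stability is
    reclassified from the scaled energy.
    """
    for pos, w in weights.items():
        if not 0.0 <= w <= 1.0:
            raise ColbindError(f"accessibility weight at position {pos} outside [0, 1]: {w}")
    kt = table.parameters.get("kt", KT_REF)
    new_sites = []
    for s in table.sites:
        positions = (s.target_start, s.target_start + 1, s.target_start + 2)
        try:
            mean_w = sum(weights[p] for p in positions) / 3.0
        except KeyError as exc:
            raise ColbindError(
                f"missing accessibility weight for target position {exc.args[0]}"
            ) from None
        dg = s.result.dg * mean_w
        new_sites.append(
            replace(
                s,
                result=InteractionResult(
                    dg=dg,
                    regime=s.result.regime,
                    stability=classify_stability(dg, kt),
                ),
            )
        )
    return ScanTable(
        sites=new_sites,
        per_position_min=_position_minima(new_sites),
        parameters={**table.parameters, "accessibility": True},
    )


def _single_edits(peptide: str, edit_set) -> list[tuple[str, str]]:
    """(sequence, edit description) for every insertion and substitution."""
    residues = sorted(set(edit_set))
    out = []
    for res in residues:
        for pos in range(1, len(peptide) + 2):  # insert before pos; len+1 appends
            seq = peptide[: pos - 1] + res + peptide[pos - 1 :]
            out.append((seq, f"ins {res}@{pos}"))
        for pos in range(1, len(peptide) + 1):
            seq = peptide[: pos - 1] + res + peptide[pos:]
            out.append((seq, f"sub {res}@{pos}"))
    return out


def design_variants(
    peptide: str,
    target: str,
    ph_list,
    edit_set,
    scale: HydropathyScale | None = None,
    policy: ProtonationPolicy | None = None,
    kt: float = KT_REF,
) -> list[DesignCandidate]:
    """Rank all single-residue insertions/substitutions by pH robustness.

    The score of a candidate is the worst over ``ph_list`` of its best site
    energy against the target; the list is sorted ascending (most robustly
    favorable first), ties broken by shorter edit description then by
    sequence.
    """
    peptide = _validate_protein(peptide, "peptide")
    if not edit_set:
        raise ColbindError("empty edit set")
    if not ph_list:
        raise ColbindError("need at least one pH to score robustness")
    for res in edit_set:
        if res not in CANONICAL_RESIDUES:
            raise ColbindError(f"non-canonical residue {res!r} in edit set")
    candidates = []
    for seq, edit in _single_edits(peptide, edit_set):
        tables = multi_ph_scan(seq, target, ph_list, scale=scale, policy=policy, kt=kt)
        robustness = max(t.min_dg() for t in tables.values())
        candidates.append(DesignCandidate(sequence=seq, edit=edit, robustness=robustness))
    return sorted(
        candidates, key=lambda c: (c.robustness, len(c.edit), c.sequence)
    )
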