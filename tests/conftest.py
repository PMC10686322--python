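"""Shared fixtures and an independent brute-force oracle for scan results."""

from __future__ import annotations

import itertools

import pytest

from colbind.interaction import TripeptideWindow
from colbind.scale import default_policy, load_default_scale


@pytest.fixture(scope="session")
def scale():
    return load_default_scale()


@pytest.fixture(scope="session")
def policy():
    return default_policy()


@pytest.fixture(scope="session")
def win(scale):
    """Factory: build a peptide-side window from state labels."""

    def _make(*labels, start=1, source="peptide"):
        return TripeptideWindow(
            source=source, start=start, states=tuple(scale.state(l) for l in labels)
        )

    return _make


@pytest.fixture
def write_fasta(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records)
        )
        return path

    return _write


def oracle_position_minima(peptide: str, target: str, ph: float) -> dict[int, float]:
    """Brute-force per-target-position minima, independent of the scanner.

    Re-derives window means, electron-density signs and the three regime
    rules from the raw scale table with plain nested loops.
    """
    scale = load_default_scale()
    pol = default_policy()

    def options(residue):
        return [scale.state(lab) for lab in pol.allowed_labels(residue, ph)]

    def window_combos(seq, i0):  # i0 0-based
        return list(itertools.product(*[options(r) for r in seq[i0 : i0 + 3]]))

    def energy(states_a, states_b):
        ma = sum(s.dg_woct for s in states_a) / 3.0
        mb = sum(s.dg_woct for s in states_b) / 3.0
        if ma < 0 and mb < 0:
            return -(abs(ma) + abs(mb))
        if (ma < 0) != (mb < 0):
            return min(abs(ma), abs(mb))
        sa = sum(s.electroneg * abs(s.dg_woct) for s in states_a)
        sb = sum(s.electroneg * abs(s.dg_woct) for s in states_b)
        if (sa > 0 and sb < 0) or (sa < 0 and sb > 0):
            return -min(abs(ma), abs(mb))
        return abs(ma) + abs(mb)

    minima: dict[int, float] = {}
    for t0 in range(len(target) - 2):
        best = None
        for p0 in range(len(peptide) - 2):
            for sb in window_combos(target, t0):
                for sa in window_combos(peptide, p0):
                    dg = energy(sa, sb)
                    if best is None or dg < best:
                        best = dg
        minima[t0 + 1] = best
    return minima
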