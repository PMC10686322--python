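# Methods

## Model

`colbind` predicts single-site peptide–protein binding from sequence alone.
The interaction unit is a pair of tripeptide windows, one on the peptide and
one on the target, both read N→C with step 1 (a length-n chain contributes
n−2 overlapping windows). Each residue state carries its Wimley–White
water→octanol side-chain transfer free energy ΔG_woct; the window hydropathy
is the arithmetic mean of its three values. Octanol is idealized as a
completely apolar phase, so a negative mean marks a window that would rather
sit against another hydrophobic surface than against water.

Two polar windows interact through a coarse electrostatic complementarity
term. Each state has an electron-density sign (−1 electron-rich: acidic,
amide, hydroxyl side chains; +1 electron-poor: basic/charged-positive side
chains plus the small low-electron-density G, P, A; 0 apolar), and a
window's sign is the sign of the |ΔG_woct|-weighted sum, so a strongly
charged state (E−, |ΔG| = 3.63) outweighs a weaker opposite one (R+, 1.81)
in the same window.

The three scoring regimes on window means mₐ, m_b:

1. mₐ < 0 and m_b < 0 → ΔG = −(|mₐ| + |m_b|). Hydrophobic burial is
   additive: pairing removes two unfavorable water contacts.
2. exactly one mean < 0 → ΔG = +min(|mₐ|, |m_b|). The polar side's excess
   electron-density heterogeneity is better absorbed by solvent.
3. mₐ ≥ 0 and m_b ≥ 0: opposite window signs give ΔG = −min(|mₐ|, |m_b|)
   (complementary densities cancel up to the weaker partner); equal or
   indeterminate signs give ΔG = +(|mₐ| + |m_b|).

The score is symmetric, and exactly one regime applies to every pair. A
window mean of exactly 0 is routed to the non-negative branch (the
hydrophobic rules use strict `< 0`). A purely apolar window (sign 0) with a
non-negative mean counts as "same sign" when paired with any other
non-negative window: with no charge heterogeneity there is nothing to
complement, so the pairing is repulsive.

Stability is judged against the thermal fluctuation scale kT:
ΔG < −kT → *stable* (the reverse reaction is unlikely to find the needed
energy), −kT ≤ ΔG < 0 → *marginal* (favorable but reversible),
ΔG ≥ 0 → *unfavorable*.

## Parameters

* **Hydropathy scale** — the embedded water→octanol transfer free energies
  (kcal/mol) with explicit charge states: L −1.25, G +1.15, H0 +0.11,
  H+ +2.33, K+ +2.80, R+ +1.81, E0 +0.11, E− +3.63, D0 +0.43, D− +3.64, …
  Every value is overridable via the flat config file
  (`scale.<state_label> = <kcal/mol>`).
* **kT reference** — 0.693 kcal/mol at 25 °C, scaling linearly with absolute
  temperature (0.721 at 37 °C, ≈4 % larger). The reference is kept at the
  conventional value used with this screen and is configurable (`kt_ref`);
  note k_B·298.15 K is 0.593 kcal/mol, so the default is a deliberate
  convention, not the physical constant.
* **Protonation policy** — a step table over exactly pH {2, 4, 7, 9}:
  D/E neutral only at pH 2, charged from pH 4 up; H protonated at pH 2 and 4,
  both H0 and H+ enumerated at pH 7, H0 only at pH 9; K/R charged
  throughout (side-chain pKa above the supported range). Intermediate pH
  values are rejected rather than interpolated — the screen is defined at
  these four conditions, and fractional (Henderson–Hasselbalch) occupancies
  would break the discrete state enumeration. An optional switch
  (`default_policy(acidic_dual_ph4=True)`) enumerates both neutral and
  charged acid states at pH 4, since that pH sits near the acids' pKa.
* **Electron-density sign table** — fixed as listed above; exposed through
  `electroneg.<state_label>` config keys. The signs of the uncharged polar
  residues are the least constrained part of the model; the shipped table
  reproduces the expected qualitative pairings (K⁺↔E⁻ attraction, LRE↔GPQ
  attraction, TKK↔GPQ repulsion) and the ≤0.2 kcal/mol near-degeneracy of
  the two LRR-10 sites.

## Scanning, comparison and design

`scan_pair` enumerates every peptide window × target window × protonation
state combination (full Cartesian product of allowed states within each
window; a window with two histidines yields four combinations at pH 7) and
records per-target-position minima. Output ordering is deterministic
(target start, then peptide start, then lexicographic state labels), so TSV
outputs are byte-stable across runs.

`apply_accessibility` multiplies each site's energy by the mean of the three
target-position weights (in [0, 1]); buried residues pull their sites
towards zero and stability is reclassified from the scaled energy. The
weights are an input (e.g. derived from a solved structure upstream); no
structure parsing happens here.

`design_variants` enumerates all single-residue insertions and substitutions
from an edit set and scores each candidate by a minimax robustness
criterion: the worst over the requested pH list of its best site energy.
This formalizes "pH-independent binder": a candidate only scores well if it
keeps a strong site at *every* pH. Ties break by shorter edit description,
then lexicographic sequence. With edit set {L} over pH {2,4,7,9} the search
recovers TKKLTLRT (insertion at position 4, robustness −1.20 kcal/mol) from
TKKTLRT.

The antisense utility translates the complementary strand of a coding
sequence (default: reverse-complement then translate 5′→3′, which maps
collagen's GPQGLLG coding region to TKKTLRT; a base-wise direct-complement
mode is also provided because the historical antisense literature is not
consistent about strand direction).

## Numerical choices

* Window hydropathy is the mean (sum/3), not the raw sum of the three
  values; the mean is what reproduces the −1.2/−0.5 kcal/mol histidine
  switch and keeps the score independent of window length conventions.
* An alternate attraction formula adding a `max−min` spread term to regime 3
  is retained behind `single_site_dG(..., attraction_spread_term=True)` for
  investigation; it is not the default because it breaks the observed
  near-equality (≤0.2 kcal/mol) of the charge-complementary and hydrophobic
  LRR-10 sites.
* Energies are kept at full float precision internally; TSVs print a
  3-decimal display column plus a full-precision column (`repr`), so a
  written table reloads bit-exactly.
* Comparisons to one-decimal reference energies use one-decimal rounding.
* Terminal amine/carboxyl charges and the proline→hydroxyproline
  modification of collagen are ignored; hydroxylation would make those
  windows more electron-rich, so hydrophobic pairings are, if anything,
  under-reported.

## Synthetic test sequences

Property tests draw random protein sequences uniformly over the 20 canonical
residues (seeded, reproducible). Uniform composition is deliberately harsher
than real collagen (no Gly-X-Y periodicity, no composition bias), which is
appropriate for what those tests check — agreement of the scanner with a
brute-force enumeration oracle and algebraic invariants of the score — and
they are run on 6–12-mers where exhaustive enumeration is cheap. Passing
them demonstrates correctness of the enumeration and scoring machinery, not
predictive accuracy on real collagen; the anchor tests on the printed
peptide/collagen fragments carry that weight.

## Limitations

* Single-site model: no cooperativity between sites, no geometry,
  conformation or distance terms, and both chains are scanned N→C only
  (antiparallel pairing is not considered).
* The screen is tuned to be low-false-negative; positive predictions should
  be filtered by accessibility weighting and confirmed by docking or
  experiment.
* The pH policy is discrete; conditions between the four supported pH values
  are out of scope by design.
* Only the octanol-scale parameterization ships; the scale container is
  pluggable via config but no alternative scale is bundled.
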