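# colbind

pH-aware screening of peptide–protein binding sites from sequence alone,
built for collagen-binding peptide engineering.

Short collagen-binding peptides (CBDs) such as TKKTLRT are widely used as
fusion tags that anchor growth factors or imaging labels to type I collagen.
Designing better ones by docking every candidate is expensive; `colbind`
instead scores every three-residue window of a peptide against every
three-residue window of a target chain using side-chain hydropathy, and flags
the window pairings whose predicted free energy of binding falls below the
thermal fluctuation scale. The screen is deliberately cheap and
low-false-negative: it is an enrichment filter in front of docking, not a
replacement for it.

## The model

Each residue state carries its Wimley–White water→octanol side-chain
transfer free energy ΔG_woct (kcal/mol, negative = hydrophobic). The scale
has distinct entries for the charge states of ionizable side chains (D0/D−,
E0/E−, H0/H+, K+, R+), and a protonation policy selects which states exist
at pH 2, 4, 7 or 9 (e.g. only D0/E0 at pH 2; both H0 and H+ enumerated at
pH 7; H0 only at pH 9).

A window of three consecutive residues has mean hydropathy
m = (ΔG₁ + ΔG₂ + ΔG₃)/3 and an electron-density sign
s = sgn(Σᵢ eᵢ·|ΔGᵢ|), where eᵢ ∈ {−1, 0, +1} marks electron-rich,
apolar and electron-poor side chains. For a peptide window a and a target
window b the single-site interaction energy is

* both hydrophobic (mₐ < 0 and m_b < 0):  ΔG = −(|mₐ| + |m_b|)
* mixed (exactly one mean < 0):           ΔG = +min(|mₐ|, |m_b|)
* both polar, opposite signs (sₐ·s_b<0):  ΔG = −min(|mₐ|, |m_b|)
* both polar, same sign:                  ΔG = +(|mₐ| + |m_b|)

Sites with ΔG < −kT (kT = 0.693 kcal/mol at 25 °C, 0.721 at 37 °C) are
classified *stable* (rarely reversible), favorable sites above −kT are
*marginal*, and ΔG ≥ 0 is *unfavorable*.

The canonical illustration is the leucine-rich-repeat peptide LRR-10
(LRELHLNNN) against the collagen fragment GPQGLLG: its L-H-L window scores
−1.2 kcal/mol against G-L-L with neutral histidine but only −0.5 kcal/mol
when the histidine protonates, so its binding is a pH switch. Replacing the
histidine-dependent site with L-T-L and splicing it into TKKTLRT (one
leucine insertion → TKKLTLRT) yields a site of −1.2 kcal/mol that no pH in
2–9 can turn off.

## Worked example

```
$ printf '>COL_frag\nGPQGLLG\n' > target.fa
$ printf '>TKKTLRT\nTKKTLRT\n>TKKLTLRT\nTKKLTLRT\n>LRR-10\nLRELHLNNN\n' > peptides.fa
$ colbind compare --peptides peptides.fa --target target.fa --ph 2,4,7,9 --out cmp.tsv
$ cut -f1,3,4,5 cmp.tsv
peptide_id	ph	min_dg	n_stable
TKKTLRT	2.0	0.27	0
TKKTLRT	4.0	0.27	0
TKKTLRT	7.0	0.27	0
TKKTLRT	9.0	0.27	0
TKKLTLRT	2.0	-1.2	2
TKKLTLRT	4.0	-1.2	2
TKKLTLRT	7.0	-1.2	2
TKKLTLRT	9.0	-1.2	2
LRR-10	2.0	-0.6866666666666666	0
LRR-10	4.0	-0.6866666666666666	0
LRR-10	7.0	-1.2466666666666666	2
LRR-10	9.0	-1.2466666666666666	2
```

Reading the table: the sense/antisense tag TKKTLRT never scores a favorable
site against this fragment (best +0.27 kcal/mol, within kT of zero — weak,
reversible binding at best). LRR-10 reaches −1.25 kcal/mol, but only at
pH 7/9 where its neutral histidine exists; at acidic pH its best site is
marginal. The engineered TKKLTLRT holds two stable sites (the L-T-L window
against G-L-L and L-L-G, −1.20 kcal/mol) at every pH.

Other commands: `colbind scan` (full site table + per-position energy
profile for any FASTA target, with optional accessibility weights),
`colbind design` (rank all single-residue insertions/substitutions by their
worst-over-pH best energy; it recovers TKKLTLRT from TKKTLRT with edit set
`L`), and `colbind antisense` (translate the complementary strand of a
coding sequence — `--nt GGTCCTCAAGGTCTTCTTGGT` prints `TKKTLRT`).

The same operations are available as a library:

```python
from colbind import scan_pair, multi_ph_scan, kT
table = scan_pair("LRELHLNNN", "GPQGLLG", ph=9)
table.per_position_min   # {1: -0.6867, 2: -0.6867, 3: -0.2233, 4: -1.2467, 5: -1.2467}
```

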