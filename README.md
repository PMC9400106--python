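# taamkit

Atom-type analysis for multipolar pseudoatom banks.

Transferable aspherical atom model (TAAM) databanks describe the electron
density of an *atom type* — an equivalence class of atoms sharing a local
chemical topology — with Hansen–Coppens multipole parameters:

ρ(**r**) = ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_l κ′³ R_l(κ′r) Σ_m P_lm d_lm(θ,φ)

where `P_val` and `P_lm` are valence and deformation populations
(electrons), `κ`/`κ′` contraction–expansion parameters, and `d_lm`
density-normalized real spherical harmonics expressed in a *local
coordinate system* anchored on the neighboring atoms. Because the `P_lm`
depend on that frame, comparing atom types across a bank requires
re-expressing every type in a common set of frames.

`taamkit` implements that analysis end to end, for crystallographers and
force-field developers who maintain or mine such banks:

* **bank I/O** — a documented plain-text dialect for atom-type entries
  (topology, frame, parameters with sds), plus CSV export;
* **frame machinery** — enumeration of all local coordinate systems per
  neighbor-count group (1x/1p/2x/2p/3p/3n/4n/6n → 1/1/2/6/12/16/40/1
  systems), their realization on geometries, and exact rotation of `P_lm`
  between frames (validated against an electron-density grid oracle);
* **site symmetry** — allowed `(l,m)` sets per point group (1, m, mm2, 3m,
  −6m2, −43m, cylindrical) derived by group projection, and detection of
  the highest symmetry consistent with a population vector;
* **topology trees** — extended/general/concise hierarchies of types by
  element and neighbor shells, with DOT/JSON export and density-cluster
  overlays;
* **density clustering** — 18-dimensional multi-level DBSCAN with
  knee-method Eps, subtraction/normalization transforms, and an
  sd-triggered subdivision protocol;
* **a synthetic bank generator** — seeded, with planted elements, groups,
  hybridizations, symmetries and noise, providing ground truth for every
  stage.

## Worked example

Generate a synthetic bank, re-express every type in all frames of its
group, and cluster:

```sh
$ taamkit simulate --seed 7 --out demo
wrote 54 atom types to demo/bank.txt
$ taamkit rotate --bank demo/bank.txt --members demo/members.json --out demo
526 rotated entries (census total 526)
$ taamkit cluster --rotated demo/rotated.csv --out demo
28 leaf clusters, 0 outlier rows
```

The 54 types expand to 526 (type × frame) entries — e.g. each of the six
tetrahedral (4n) carbon types contributes 40 rows, one per coordinate
system. `demo/report.csv` summarizes each density cluster; the first rows:

```
 cluster  n dominant_multipole  dominant_value point_group
       0  5                P10        0.277713 cylindrical
       1  5                P10        0.121454 cylindrical
      13 18                P32       -0.260382           m
      14  6                P30       -0.219026          3m
```

Clusters 0 and 1 are the polar and nonpolar hydrogens: cylindrical
symmetry, dominant positive dipole along the bond, the polar ones more
strongly so. Cluster 13 collects sp³ carbon rotations in pair-bisector
(ZabXc) frames — dominant *negative* P32, the signature of a tetrahedral
deformation in that orientation — and cluster 14 shows pyramidal nitrogen
in its three-fold (ZabcXa) frame with 3m symmetry. The level-1 Eps found
by the knee method (0.038 here) and every sub-run Eps are recorded in
`demo/manifest.json`.

`taamkit tree --bank demo/bank.txt --kind general --assignments
demo/assignments.csv --out demo` writes the topology tree with the density
clusters overlaid as color categories (main / distinct / unique / outlier).

The same pipeline accepts a real bank file in the documented dialect
(`docs/bank_format.md`); without member-atom geometries, `rotate` falls
back to idealized group geometries, and `cluster --eps-schedule FILE`
replays a fixed multi-level Eps schedule.

## Layout

```
src/taamkit/
  bank.py            atom-type records, text dialect, storage filter
  harmonics.py       density-normalized real spherical harmonics + rotation
  hansen_coppens.py  pseudoatom density evaluation (the rotation oracle)
  frames.py          local-coordinate-system enumeration and realization
  symmetry.py        point-group projectors and symmetry detection
  topology.py        extended/general/concise trees, overlay, DOT/JSON
  clustering.py      transforms, knee Eps, DBSCAN, multi-level protocol
  synthetic.py       seeded generator with planted ground truth
  pipeline.py        bank → rotated table → clusters orchestration
  cli.py             taamkit simulate | rotate | cluster | report | tree
```

See `docs/methods.md` for the model conventions, numerical choices and
limitations.
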