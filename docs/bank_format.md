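# Bank text format

`taamkit` reads and writes atom-type banks in a line-oriented plain-text
dialect. One file holds any number of entries; each entry is a block of
key–value lines between `entry <name>` and `end`. The first line of the
file must be the header `# taamkit bank 1`. Blank lines and lines starting
with `#` are ignored elsewhere.

## Grammar

```
bank        := header entry*
header      := "# taamkit bank 1" NL
entry       := "entry" NAME NL
               "element" ELEMENT NL
               "group" GROUP NL
               "frame" FRAME_NAME NL
               ("inconsistent" ("yes"|"no") NL)?
               neighbor*
               "kappa" FLOAT FLOAT NL          ; value, sample sd
               "pval" FLOAT FLOAT NL
               "kappa_prime" FLOAT FLOAT NL
               plm*
               "end" NL
neighbor    := "neighbor" SHELL LABEL ELEM_OR_X
               ("planar")? ("rings=" INT ("," INT)*)? ("attach=" LABEL)? NL
plm         := "plm" L M FLOAT FLOAT NL        ; value, sample sd
GROUP       := "1x"|"1p"|"2x"|"2p"|"3p"|"3n"|"4n"|"6n"
SHELL       := "1"|"2"|"3"
L           := 0..4 ;  M := -L..L
```

* `ELEMENT` is a supported element symbol; `ELEM_OR_X` additionally allows
  the any-element wildcard `X` for neighbors.
* First-shell neighbors are labeled `a`, `b`, `c`, … in the order bonds are
  engaged by coordinate systems (descending atomic number, ties broken by
  input order). Second-shell records must name the first-shell label they
  attach to via `attach=`.
* `rings=` lists memberships in 3-/4-membered rings and planar 5-/6-/7-
  membered rings.
* `frame` names the local coordinate system the stored `plm` values refer
  to, e.g. `4n_41-ZabXc` (see `taamkit.frames` for the naming scheme).
* All populations are in electrons; `kappa`/`kappa_prime` dimensionless.

## Canonical form and round-tripping

`write_bank` emits one canonical rendering: keys in the order above,
floats with six decimals, `plm` lines sorted by `(l, m)`. For documents in
canonical form, `write_bank(parse_bank(text)) == text` bit-exactly.

## Validation

Parsing validates each entry: the group label must match the number of
first-shell records, every second-shell record must attach to a declared
first-shell label, `(l, m)` indices must satisfy `l <= 4`, `|m| <= l`, every
stored `plm` needs an sd, and the `inconsistent` flag must equal
"some Plm sd exceeds 0.05 e". Violations raise `BankError` naming the
entry and line.
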