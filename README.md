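# ddckit

Hierarchical data access on reconfigurable DNA domino-array carriers: a
tested software model of storing messages as biotin/streptavidin label
patterns on DNA origami, unlocking them with administrator (polymerase) or
user (DNA strand-set) keys, reading them back from noisy spot fields, and
quantifying access success.

## The system

A **DNA-based data carrier (DDC)** is a rectangular origami domino array
whose lattice of four-way anti-junctions can flip between two
conformations.  Thirty staple sites form the data array: a 5 × 5 message
block plus a 1 × 5 address row above it.  A site carrying a biotin-modified
staple is bit **1** (streptavidin binds there and shows up as a bright
spot); a plain staple is bit **0**.  In the locked **OFF** conformation the
label lattice is compact and the stored pattern — whose columns are
additionally permuted by an address-keyed scramble — reads as ciphertext.
Unlocking the carrier (removing its 13 displaceable edge staples and
resolving its scaffold gap regions) stretches the lattice into the **ON**
conformation, after which the address row tells the reader how to invert
the permutation and recover the plaintext.

Two key classes trigger the unlocking:

* **Admin key** — a strand-displacing polymerase.  It acts on primer-bound
  regions regardless of sequence, so one admin key opens *every* carrier
  (one-to-many).
* **User key** — a trigger-strand set whose competing strands complement
  the carrier's scaffold gap regions and whose invading strands complement
  its edge-staple overhangs.  Sequence complementarity makes it one-to-one
  with its carrier.

Because a carrier's gap and overhang sequences are read off the circular
scaffold at its breakpoint, shifting the breakpoint mints a new user key:
an M13mp18-length scaffold (7,249 nt) supports thousands of candidate keys,
screened for pairwise orthogonality with a shared k-mer rule.

Access success is scored per structure as **CorrInfo**: the carrier is ON
*and* every bit reads correctly.  Its expected rate follows

```
y_exp  = M / N                (observed: M successes among N structures)
y_theo = p · qⁿ               (model: p = ON-conformation yield of the key,
                               q = per-site streptavidin binding success,
                               n = number of biotin sites in the pattern)
```

so denser patterns (larger *n*) are intrinsically harder to read perfectly.

## Worked example

```python
>>> from ddckit import *
>>> grids = encode_message("DNA NANO TECH")        # 3 carriers, one per word
>>> render_ciphertext(grids[0])                    # locked carrier: ciphertext
'D S B'
>>> decode_grids(grids).text                       # keyed access: plaintext
'DNA NANO TECH'

>>> scaf = default_scaffold()
>>> ddc1, ddc2 = standard_designs(scaf)            # two users, same scaffold
>>> admin, user1, user2 = standard_keys(scaf)
>>> matches(admin, ddc1), matches(admin, ddc2)     # admin: one-to-many
(True, True)
>>> matches(user1, ddc1), matches(user1, ddc2)     # user: one-to-one
(True, False)

>>> n = count_biotin_sites(grids[0])               # "DNA" pattern: 5 biotin sites
>>> yield_theo(0.89, 0.95, n).y_theo               # matched user key model
0.6887
>>> ens = simulate_ensemble(ddc1, grids[0], user1, ReadoutParams(),
...                         10_000, seed=42, keep_fields=False)
>>> ens.corrinfo_fraction                          # Monte-Carlo agrees
0.6893
>>> ens.tally
{'OFF': 621, 'ON': 8896, 'IC': 483}

>>> enumerate_breakpoint_keys(scaf, min_shift_nt=1).count
7249
```

The simulated CorrInfo rate (0.6893) matches the analytic yield
0.89 · 0.95⁵ = 0.6887; the ON tally reflects the 89% transformation yield
of a matched user key, with a small fraction of structures stalled in the
intermediate (IC) conformation.

A command-line interface wraps the same pipeline:

```
ddckit encode --text "DNA NANO TECH" --out grids.json
ddckit decode --grids grids.json
ddckit keygen --design DDC-1 --out key.json
ddckit keyspace --length 7249 --min-shift 1
ddckit simulate --design DDC-1 --text DNA --key user --n 100 --out fields
ddckit decode-field --spots fields/w0_s00000.csv --design DDC-1
ddckit experiment --config multiuser --out results/
```

## Layout

- `ddckit.codec` — text ↔ bit grids, addressing, scramble/descramble
- `ddckit.carrier` — carrier geometry, marker pair, conformation states
- `ddckit.access` — admin/user keys, matching, key-space enumeration
- `ddckit.simulate` — stochastic readout simulator and fixture generator
- `ddckit.decode` — conformation classification, bit calling, recovery
- `ddckit.stats` — y_exp / y_theo, condition and permission-matrix harnesses
- `docs/methods.md` — model assumptions, parameters and limitations
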