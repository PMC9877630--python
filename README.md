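# goldengate

An in-silico Golden Gate cloning toolkit for the pBTR plant binary-vector
system: type-IIS (BsaI) restriction-site discovery and digestion, one-pot
one-way digestion–ligation simulation, adapter-tailed primer design,
recombinant-plasmid prediction, and colony-colour / restriction-map
screening.

## What it does

* **`goldengate.seq_model`** — DNA records (linear/circular, 0-based
  half-open coordinates), sticky fragments with explicit 5′/3′ overhangs,
  strand arithmetic, FASTA/GenBank I/O.
* **`goldengate.digestion`** — recognition-site scanning on both strands
  (including across circular origins), digestion into sticky fragments
  with exact cut geometry (BsaI: `GGTCTC(N1)/(N5)` → 4-nt 5′ overhangs),
  restriction maps, and a built-in classical-enzyme table (HindIII, XbaI,
  EcoRI, SacI/II, PstI, BamHI, XhoI, SalI, PmeI).
* **`goldengate.assembly`** — enumeration of circular ligation products
  (exact reverse-complement annealing, rotation/reflection deduplication),
  the cycled one-pot reaction with its two terminal-hold variants
  (4 °C/1 h ligation hold for inserts carrying internal sites;
  37 °C/10 min digestion hold that suppresses empty vectors), multiplexed
  reactions, product classification (desired / empty vector / cassette
  circle / chimera / concatemer), and classical subcloning replay.
* **`goldengate.design`** — Table-driven adapter primers
  (`NNNN GGTCTC N <4-mer> + 18–28 nt gene-specific`), vector-set selection
  against internal-overhang collisions, molar-ratio and terminal-hold
  planning, and C-terminal eGFP fusion ORFs with the GGSGGS linker.
* **`goldengate.screening`** — colony-colour prediction from
  selection-cassette intactness (reddish-pink vs white) and band-by-band
  restriction-map screening.
* **`goldengate.registry`** — the 32-vector pBTR registry (sets BTR1/BTR2,
  adapter pairs, overhangs, plant markers), plus deterministic synthetic
  generators: FDIs with a controlled internal BsaI site architecture,
  toy CDSs, and mock destination vectors.

Full plasmid sequences are not redistributed; user-supplied GenBank files
can be attached to registry entries and are validated. Everything
sequence-level runs on generated mock vectors.

## CLI

```sh
goldengate vectors                           # list the vector registry
goldengate design --fdi gene.fasta --vector pK35BTR1 --out-config rx.json
goldengate digest --in plasmid.gb --enzymes BsaI,HindIII --map
goldengate simulate --config rx.json --records vec.gb --records amp.fasta \
    --out-dir products/
goldengate verify --plasmid clone.gb --cassette cassette.fasta \
    --enzymes HindIII --expect 3846,1200 --tolerance 50
goldengate fixtures --set BTR2 --out fixtures/ --seed 1 --internal-sites 2
```

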