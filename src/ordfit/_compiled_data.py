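"""Encoded compiled dataset: 25 ordinal observations of the anterior germarium.

Each row records the measured species, the genetic condition, the data
category and the per-region ranks (1 = low, 2 = high; regions omitted from
``ranks`` are masked).  The published compilation prints the experiment /
measurement pairs and the category assignments; the per-region rank values
are an editorial encoding of the qualitative interpretations shown for
example images and described in the source literature — each row's ``note``
states the interpretation it encodes.

Encoding conventions:
- Phenotype rows encode fusome morphology on the derived time-averaged Brat
  output: spectrosome = rank 1, fusome = rank 2.
- Bam rows mask the Posterior region (posterior repression by RBP9 is
  unmodeled); Nos rows mask the Posterior region (re-expression in late
  cysts is unmodeled).
"""

COMPILED_ROWS = [
    dict(index=1, species="Nos", condition="WT", category="WildType", dynamic=False,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1},
         note="editorial: Nos high in GSC, low in CB/cysts (Casanueva 2004); "
              "Posterior masked (late-cyst re-expression unmodeled)"),
    dict(index=2, species="pMad", condition="WT", category="WildType", dynamic=False,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: pMad anterior-high, restricted to GSC"),
    dict(index=3, species="Bam", condition="WT", category="WildType", dynamic=False,
         ranks={"GSC": 1, "CB": 2, "Cyst": 2},
         note="editorial: Bam absent in GSC, expressed in CB/cysts; "
              "Posterior masked (RBP9 repression unmodeled)"),
    dict(index=4, species="Phenotype", condition="WT", category="WildType", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: spectrosome in GSC/CB, branched fusome in cysts"),
    dict(index=5, species="Phenotype", condition="Bam-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: bam mutant germaria fill with spectrosome cells"),
    dict(index=6, species="pMad", condition="Bam-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: pMad does not extend beyond the anterior in bam mutants"),
    dict(index=7, species="Nos", condition="Bam-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 2, "Cyst": 2, "Posterior": 2},
         note="editorial: Nos uniformly high in bam mutants (Li 2009)"),
    dict(index=8, species="pMad", condition="dMyc OE", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: ectopic dMyc leaves the anterior-restricted pMad "
              "pattern intact (Rhiner 2009)"),
    dict(index=9, species="pMad", condition="dMyc-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: pMad reduced without dMyc (Rhiner 2009)"),
    dict(index=10, species="Phenotype", condition="dMyc+/-", category="Behavioral", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: negative phenotype — heterozygote remains wild-type-like"),
    dict(index=11, species="pMad", condition="dMyc-/- dMyc OE", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 2, "Cyst": 2, "Posterior": 1},
         note="editorial: ectopic dMyc in a dMyc null broadens pMad "
              "(Rhiner 2009); consistently poorly fit"),
    dict(index=12, species="Brat", condition="WT", category="WildType", dynamic=False,
         ranks={"GSC": 1, "CB": 2, "Cyst": 2, "Posterior": 2},
         note="editorial: Brat low in GSC, expressed from the CB on (Harris 2011)"),
    dict(index=13, species="Brat", condition="Bam-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: Brat uniformly low without Bam (Harris 2011)"),
    dict(index=14, species="Brat", condition="Nos-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 2, "Cyst": 2, "Posterior": 2},
         note="editorial: Brat uniformly high in nos mutants (Harris 2011)"),
    dict(index=15, species="pMad", condition="Brat-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 2, "Cyst": 2, "Posterior": 1},
         note="editorial: pMad extends beyond the CB in brat mutants "
              "(Harris 2011); Cyst-wide extent possibly over-aggressive"),
    dict(index=16, species="Bam", condition="Brat-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 1, "CB": 2, "Cyst": 2},
         note="editorial: Bam pattern wild-type-like in brat mutants; "
              "Posterior masked as in WT"),
    dict(index=17, species="Phenotype", condition="Dpp-/-", category="Mutant", dynamic=False,
         ranks={"GSC": 2, "CB": 2, "Cyst": 2, "Posterior": 2},
         note="editorial: without Dpp all germline cells differentiate (Xie 1998)"),
    dict(index=18, species="Phenotype", condition="Dpp+/-", category="Behavioral", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: negative phenotype — Dpp heterozygote wild-type-like "
              "(Xie 1998); consistently poorly fit"),
    dict(index=19, species="Phenotype", condition="Bam+/-", category="Behavioral", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: negative phenotype — Bam heterozygote wild-type-like "
              "(Shen 2009)"),
    dict(index=20, species="Phenotype", condition="Nos+/-", category="Behavioral", dynamic=False,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: negative phenotype — Nos heterozygote wild-type-like "
              "(Maines 2007)"),
    dict(index=21, species="pMad", condition="WT", category="Behavioral", dynamic=True,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1, "Posterior": 1},
         note="editorial: wild-type pMad pattern re-established within a cell "
              "cycle after division/displacement (Morris 2011)"),
    dict(index=22, species="Bam", condition="WT", category="Behavioral", dynamic=True,
         ranks={"GSC": 1, "CB": 2, "Cyst": 2},
         note="editorial: wild-type Bam pattern re-established post division; "
              "Posterior masked as in WT"),
    dict(index=23, species="Nos", condition="WT", category="Behavioral", dynamic=True,
         ranks={"GSC": 2, "CB": 1, "Cyst": 1},
         note="editorial: wild-type Nos pattern re-established post division; "
              "Posterior masked as in WT"),
    dict(index=24, species="Brat", condition="WT", category="Behavioral", dynamic=True,
         ranks={"GSC": 1, "CB": 2, "Cyst": 2, "Posterior": 2},
         note="editorial: wild-type Brat pattern re-established post division"),
    dict(index=25, species="Phenotype", condition="WT", category="Behavioral", dynamic=True,
         ranks={"GSC": 1, "CB": 1, "Cyst": 2, "Posterior": 2},
         note="editorial: wild-type fusome pattern re-established post division"),
]
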