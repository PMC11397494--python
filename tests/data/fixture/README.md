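# Frozen expectations for the deterministic fixture

These TSVs are the expected end-to-end outputs of
`cneaccel.fixture.run_fixture_pipeline()`.  The fixture dataset is entirely
constructed, synthetic data (see `cneaccel/fixture.py`); every number below
was verified by hand arithmetic before freezing.

## Catalog (`catalog.tsv`)

Planted conserved stretches on the 2000-bp reference chromosome and what the
pipeline must do with them:

| stretch      | hand-derived outcome |
|--------------|----------------------|
| [70,130)     | overlaps CDS [100,220) of g0001 → trimmed to [70,100), length 30, kept (CNE00001, nearest g0001 at 0) |
| [300,360)    | the accelerated element: its three hermaphrodite terminals are mutated at scale ρλ = 0.3·8, so the Viterbi path exits the conserved state at column 353; called [300,353) (CNE00002, nearest g0001 body end 240 → signed distance −60) |
| [500,540)    | kept (CNE00003; g0002 starts 600 → +60) |
| [850,862)    | length 12 > 10, kept (CNE00004; g0002 ends 800 → −50) |
| [900,910)    | length 10, removed by the strictly-greater-than-10 rule |
| [1000,1060)  | kept on the reference; C_latens carries a 70-column insertion → projection 1000–1130, length 130 > 2×60 → `dropped_length_ratio` for C_latens only |
| [1200,1260)  | kept; a second alignment block maps the C_brenneri copy to chrB:5000–5060, so its projection is two disjoint intervals → `dropped_redundant` for C_brenneri only |
| [1600,1700)  | kept (CNE00007; g0004 starts 1750 → +50) |

## Nucleotide diversity (`pi_per_element.tsv`, `pi_summary.tsv`)

8 haplotypes; per site the unbiased estimator `2p(1−p)·n/(n−1)` with n the
non-missing haplotypes. Hand values (exact fractions):

- CNE00002 [300,353): one site, 4/8 derived → (2·½·½·8/7)/53 = (4/7)/53 = 0.01078167…
- CNE00006 [1200,1260): one site, 1 of 7 called (one missing) → (2·(1/7)(6/7)·7/6)/60 = (2/7)/60 = 0.00476190…
- CNE00007 [1600,1700): k=1 and k=2 sites → (¼ + 3/7)/100 = 0.00678571…
- CDS g0001 [100,220): k=4,3,4 → (4/7 + 15/28 + 4/7)/120 = 0.01398809…
- medians: CNE (4 elements > 50 bp) = mean of middle two = 0.00577381;
  CDS = 0.00625. CNE median < CDS median, as in the wild-population contrast.

## Transition table (`transitions.tsv`)

12 one-to-one orthologs; planted classes give cells
(XX,XX)=g01, (XX,Non)=g02, (XO,XO)=g03, (XO,XX)=g04, (Non,XX)=g05,
(Non,Non)=g06–g12.  Neighbors {gA04,gA05,gA07}.  E.g. the (XO,XX) cell:
2×2 = [[1,0],[2,9]], hypergeometric two-sided p = 3/12 = 0.25; odds ratio
with the +0.5 correction = (1.5·9.5)/(0.5·2.5) = 11.4.

## Acceleration

Only CNE00002 has the hermaphrodite terminals mutated; the joint LRT must
call exactly this element at q < 0.05 (all other elements are identical
across species → λ̂ = 1, p = 1).
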