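# Methods

## Measurement model

A two-channel m6A microarray measures, for every probe, the fluorescence
of the antibody-captured methylated RNA pool (IP, Cy5) and of the
unmethylated supernatant pool (Sup, Cy3). Writing $T_{g}$ for the total
abundance of transcript $g$ and $\ell_g \in (0,1)$ for its methylated
fraction, the two channels ideally report $T_g\,\ell_g$ and
$T_g(1-\ell_g)$. The pipeline's three derived quantities are

- m6A quantity $Q = \mathrm{IP}$,
- expression $E = \mathrm{IP} + \mathrm{Sup}$,
- m6A level $\ell = \mathrm{IP} / (\mathrm{IP} + \mathrm{Sup})$,

so the identities $E = Q + (E - Q)$ and $\ell = Q/E$ hold exactly by
construction, $\ell$ is invariant to any rescaling applied to both
channels, and at perfect antibody efficiency the three quantities
recover $T\ell$, $T$ and $\ell$. The vendor's exact proprietary
formulas are not public; these definitions are the reconstruction that
is consistent with "level = percentage of modified RNA per transcript"
and "quantity = methylation amount per transcript", and they are what
the conservation tests assert. No antibody-efficiency or input-fraction
calibration is modeled.

Multi-probe transcripts are collapsed by the mean of **linear-scale**
probe intensities per channel before any ratio is taken
(ratio of means); this is stabler than the mean of per-probe ratios when
some probes sit near background.

## Spike-in normalization

Arrays drift in overall intensity (labeling efficiency, scanner gain).
Exogenous spike-in RNAs at fixed known amounts provide the reference:
per sample $s$ and channel, the offset

$$o_s = \overline{\log_2 \mathrm{spike}}_s - \frac{1}{S}\sum_{s'} \overline{\log_2 \mathrm{spike}}_{s'}$$

is subtracted from every probe of that sample. The grand mean across
samples is the anchor, which makes normalized values comparable across
samples — required for cross-group fold changes — and makes the
transform idempotent. Each channel is normalized independently (the two
fractions are separately labeled and scanned signals). Normalization is
a per-sample constant shift on the log2 scale, hence monotone: probe
ordering within a sample is never changed.

Numerical choices: raw fluorescence below 1.0 unit is floored at 1.0
before log2 (scanner background guard; note this means idempotence only
holds exactly above the floor); at least two spike-in probes are
required and a spike-in flagged Absent anywhere aborts normalization
rather than silently degrading the anchor.

## Probe selection

A probe enters the analysis set if it carries flag P, M or QC in at
least one sample of either fraction. The rule is deliberately the
vendor's permissive "all targets" union — including the QC flag — and
flags gate *probe selection only*: flagged-Absent cells of a selected
probe keep their measured values downstream, mirroring how the
Excel-sheet outputs of the array platform behave. Spike-ins are always
excluded from the selected biological set and always retained internally
for normalization.

## Differential classification

Group means are taken on the log2 scale (geometric means on the linear
scale), so swapping test and reference exactly negates every log2 fold
change and up/down changes are treated symmetrically. A transcript is
hyper-methylated when $\log_2\mathrm{FC} \ge \log_2 1.5$ (inclusive;
the stated "fold change of ≥ 1.5" is read as *linear* fold change 1.5,
the conventional array cut-off — the alternative reading
$|\log_2\mathrm{FC}| \ge 1.5$ would be a 2.8-fold rule). The threshold
is a parameter. A slack of 1e-12 log2 units is applied at the boundary
so a fold change of exactly 1.5 lands on the inclusive side regardless
of floating-point path. No variance statistic is computed — the method
is fold-change-only — and designs with fewer than two replicates per
group are rejected so means stay meaningful.

Direction proportions (percent hyper vs. hypo among changed transcripts)
and all reported percentages are rounded half-up to one decimal.

## Reversal intersection

For comparisons $B$ vs $A$ (insult) and $C$ vs $B$ (treatment):
attenuation intersects {hyper in $B$ vs $A$} with {hypo in $C$ vs $B$};
enhancement intersects the complementary directions. Counts are computed
on mRNAs only (lncRNA probes are excluded), and the headline percentage
is $100\,|A\cap B|/|A\cup B|$ — the union denominator is the one
consistent with both published example pairs (613/5726 → 10.7%,
1063/8607 → 12.4%). Rounding is half-up to one decimal. A transcript can
never appear in both the attenuation and enhancement member lists for
the same pair of comparisons, since that would require it to be both
hyper and hypo in one table.

## Over-representation analysis

The enrichment p-value for a set with $K$ members in a universe of $N$
genes, given a query of $n$ genes overlapping it in $k$, is the
hypergeometric upper tail $P(X \ge k)$ (so $k=0$ gives $p=1$).
The universe is the set of flag-passing mRNA gene symbols, not the whole
genome — standard ORA practice when the assay itself defines what was
measurable. Benjamini–Hochberg correction is applied across all sets of
one collection per run; ties in $p$ are broken by descending overlap
then set name so output order is deterministic. The tail probability is
delegated to `scipy.stats.hypergeom` and BH to
`statsmodels.stats.multitest`; the test suite independently verifies the
tail against exhaustive enumeration of all $\binom{N}{n}$ draws on small
universes, and its null calibration against direct hypergeometric
sampling. Because the statistic is discrete, the attainable level just
below 0.05 (about 0.049 at $N{=}20000, K{=}4000, n{=}1000$) is the
correct reference for the type-I check, not 0.05 itself.

No GO DAG topology, term pruning, or external enrichment services are
involved.

## Concordance

The relationship between methylation and expression changes is
summarized by the Spearman rank correlation of log2 fold-change vectors
(fold changes are heavy-tailed; only a qualitative trend is claimed):
quantity vs. expression, and level vs. expression. When planted
methylation changes ride on expression changes (coupled), quantity
tracks expression strongly; the methylated fraction does not — the
rationale for using quantity in transcript-to-transcript comparisons.

## Synthetic data generator

The generator emulates the study design: three groups × triplicate
arrays, log-normal probe intensities, spike-in probes with per-array
scale drift, planted effects with known labels. Per gene: baseline
$\log_2$ total abundance $\sim \mathcal N(10, 1.5^2)$ (typical
mid-dynamic-range array signal), baseline methylated fraction uniform on
(0.2, 0.8); per array and channel a scale offset
$\sim \mathcal N(0, 0.3^2)$; per cell replicate noise
$\sim \mathcal N(0, 0.2^2)$ on the log2 scale. Planted effects shift the
log2 m6A quantity by ±2 (a 4-fold change, comfortably above the 1.5-fold
call threshold) in 16%/4% (hyper/hypo) of genes for the insult group and
15%/5% de novo for the treatment group — matching the roughly 80/20 and
75/25 direction splits such experiments report — with 20% of insult
effects reversed by treatment and 70% of changed genes coupling their
expression to the quantity shift. 10% of probes are lncRNAs (exercising
the mRNA-only reversal counts), and 2% of probe×sample cells are
"dropouts": flagged A with a small positive background intensity, since
flag filtering — not value masking — is the selection mechanism.

Design notes:

- The Sup channel is generated as total minus methylated amount, so
  IP + Sup = total holds exactly and the conservation invariant is
  testable end to end.
- Per-channel array offsets are centered to mean zero across arrays.
  This makes the grand-mean spike-in anchor unbiased, so at zero noise
  the pipeline recovers planted levels and classes *exactly* — the
  sharpest possible recovery oracle. Real arrays have no such
  constraint; with uncentered drift an overall channel-scale constant
  would survive normalization (it cancels in all fold changes but not in
  the absolute level).
- Genes planted with an expression-uncoupled upward quantity shift draw
  their baseline level below $0.95/2^{\mathrm{effect}}$ so the shifted
  methylated fraction stays below 1; consequently `effect_log2` is
  capped at $\log_2(0.95/0.05) \approx 4.25$.
- Ground-truth classes are defined by the *sign of the planted shift*,
  so exact recovery is only expected when `effect_log2` exceeds the log2
  call threshold.
- A single `numpy.random.default_rng(seed)` stream drives every draw;
  identical config and seed give bit-identical tables.

What the generator does **not** model — and what passing tests therefore
do not establish about real arrays: probe sequences and hybridization
chemistry, scanner image artifacts, probe-specific affinity differences,
antibody IP efficiency, and biological pooling variance (each real
sample is a pool of animals; the generator models arrays, not animals).
Dropout cells retain corrupted low values by design, so at the default
dropout rate a small excess of spurious calls over the planted count is
expected and visible in the worked example.

## Problem sizes

The test and acceptance runs use 300–2000 genes with triplicate arrays,
10,000 draws for the null-calibration simulation, and exhaustive
enumeration up to $N = 12$ universes — sizes at which every binomial
99% interval and correlation bound asserted is comfortably
discriminating, while the whole suite runs in seconds.

## Known limitations

- Only fold-change classification is offered; no moderated-variance or
  p-value-based differential testing for the array comparisons.
- The spike-in anchor is the grand mean, not a fixed reference value; if
  the vendor anchors differently, absolute normalized intensities differ
  by a constant (fold changes are unaffected).
- Enrichment reimplements generic hypergeometric ORA; results are not
  comparable term-for-term with external web services whose universes
  and corrections differ.
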