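# Methods

## Scheme geometry

A dia-PASEF method with `n_scans` TIMS ramps and `windows_per_scan = k` IM
windows per ramp carries `W = n_scans * k` rectangular isolation windows in
the m/z × 1/K0 plane. The geometry is fully determined by the m/z bin edges
and a trapezoidal scan area.

**m/z binning.** Equal-density edges are the empirical quantiles of the
(filtered) library's precursor m/z values at probabilities `i/W`, with the
outer edges pinned to the configured m/z range; per-bin counts then differ
by at most one unless the library has heavy ties at an edge (reported as an
error, since tied quantiles would collapse a window to zero width).
Equidistant edges (an arithmetic progression) reproduce the classic
fixed-width layout and serve as the baseline. Bins are half-open
`[start, end)` except the highest bin, which is closed, so every precursor
belongs to exactly one bin; IM intervals are closed.

**Scan area.** The covered region is a trapezoid parameterised by four
corner IM values: the lower and upper edge evaluated at the method's m/z
extremes, each edge linear in m/z. A line at relative height `f` (0 =
bottom, 1 = top) interpolates between the two edges and is itself linear in
m/z.

**Bin-to-scan assignment.** With bins indexed `1..W` from lowest m/z, scan
`j` carries in strip `s` (1 = top, highest IM) the bin
`W - (s-1)*n_scans - (j-1)`: the first scan starts at the highest-m/z bin
and every subsequent scan's starting window shifts one bin lower. This
diagonal layout follows the physical correlation between m/z and mobility —
high-m/z precursors elute at high 1/K0 — and means each m/z bin is acquired
in exactly one IM strip. A consequence worth knowing when building test
fixtures: with `k >= 2` a scheme can only fully cover clouds shaped like a
rising diagonal band whose climb over `1/k` of the m/z range exceeds its
height. Real charge-stratified precursor clouds have this shape; an
axis-aligned blob does not, and no trapezoid placement can cover it
completely.

**IM boundaries.** The boundary between strips `s` and `s+1` of scan `j`
lies on the trapezoid line at fraction `(k-s)/k`, evaluated at the mean of
the two adjacent bins' m/z centres — the quadrupole jumps once per boundary
per ramp, so a single IM value is needed, and the mean balances the two
windows against the diagonal (the evaluation point is a free design choice;
any point between the two bin centres would be defensible). Boundaries
falling outside the instrument IM range are clamped with a warning. The top
strip's upper IM and the bottom strip's lower IM are replaced by the
instrument IM limits, so the scheme never loses ions above or below the
trapezoid.

**Timing.** Cycle time = `(n_scans + ms1_frames) * (ramp_time +
frame_overhead)`. Defaults: 100 ms ramp, one MS1 frame, 6.15 ms per-frame
transfer overhead, which yields 1.38 s for the 12-scan (60 samples/day)
preset. The instrument's overhead is not a published constant; 6.15 ms is
the value consistent with the 12-scan cycle time and is configurable. The
commonly quoted 1.0 s (8 scans) and 2.7 s (25 scans) round-number cycle
times are not simultaneously consistent with any single fixed overhead; this
package treats the two-decimal 12-scan value as the anchor and reports
0.955 s / 2.76 s for the other presets.

Presets: 100/60/30 samples per day ↔ 8/12/25 dia-PASEF scans, m/z 300–1200
(proteome) or 400–1400 (phospho), IM 0.6–1.5, two IM windows per scan.

## Coverage

A precursor is covered when its (m/z, 1/K0) lies inside at least one window
(half-open m/z, closed IM, closed upper m/z limit). The default evaluation
population is charge 2–4 precursors inside the configured ranges,
unweighted; intensity weighting is opt-in. Per-window counts assign each
covered precursor to the unique window containing it. The vectorized path
is checked against a naive per-record loop in the tests.

## Optimization

The objective maps the four corner IM values to the covered fraction. Bin
edges are computed once per library and held fixed — they do not depend on
the scan area — so the search space is the 4-dimensional box of corner
values bounded by the instrument IM range. Corner orderings with
non-positive trapezoid height at either end score 0 rather than being
excluded, keeping the space a box.

The default search evaluates `n_initial_random = 20` uniform draws and then
proposes points by expected improvement under a Gaussian-process surrogate
(constant × Matern-5/2 + white-noise kernel, normalised targets, no kernel
restarts for determinism) over a pool of 512 uniform candidates plus 128
local perturbations of the incumbent (sd = 5% of the box width), up to
`n_trials = 200` total evaluations — the budget at which the search
reliably plateaus on both synthetic clouds and the recovery fixtures. All
randomness flows from one seed; two runs with identical inputs produce
identical histories. The proposer is a plain callable `(bounds, history,
rng) -> params`, so random search (provided) or any custom strategy can be
swapped in. An exhaustive grid search over the same box is included as a
deterministic test oracle.

## Synthetic clouds

The generator emulates the band structure of tryptic-digest precursor
clouds: a charge mixture (2+:0.66, 3+:0.27, 4+:0.07), m/z lognormal with
median ≈ 700 Th, and per-charge mobility trends `im ≈ 0.40 + 0.0009·mz`
(2+), `0.30 + 0.0008·mz` (3+), `0.28 + 0.00075·mz` (4+) with Gaussian
residual sd 0.045, truncated by rejection to m/z 300–1200 and IM 0.6–1.5.
The constants are free parameters chosen to visually mimic real
charge-stratified density maps, not measured values. The phospho mode
translates the cloud by (+80 Th, +0.03 1/K0) before truncation to m/z
400–1400 — the phosphate's ~80 Da mass shift and the mobility increase of
phosphopeptides — and re-weights the charge mixture toward 3+/4+
(0.50/0.38/0.12). Because the shift is a translation applied before
truncation, it is exactly testable by widening the truncation ranges.

A second generator draws points uniformly inside a prescribed trapezoid
(uniform m/z; mobility uniform between the local bottom and top edge, with
a 1% relative margin keeping points strictly interior), giving fixtures
whose optimal scan area is known by construction. The canonical recovery
fixture uses a steep thin band (bottom 0.70→1.10, top 0.85→1.30 over m/z
400–1200) precisely because, per the geometry note above, that is the cloud
shape a two-strip scheme can tile.

**What the synthetic tests do not show.** The clouds are smooth parametric
mixtures: they lack the multimodal substructure, intensity correlations,
retention-time dimension and modification-specific conformer effects of
real libraries. Passing coverage numbers on synthetic clouds therefore
validate the geometry, bookkeeping and optimizer, not instrument
performance on a particular sample; coverages on deposited libraries will
differ with the empirical cloud shape.

## Numerical and I/O choices

- Boundary precursors: a precursor on an internal m/z edge belongs to the
  higher bin; on a shared IM boundary within a scan it is covered by both
  strips in IM but only one in m/z, so it is counted once.
- Window overlap defaults to 0 Th; a symmetric overlap can be configured
  and widens windows without moving centres.
- Library round-trip uses shortest-repr floats with `round_trip` parsing,
  so the generic dialect is lossless.
- Method files print IM with six decimals and m/z with four; re-reading
  reconstructs windows at that precision and a write–read–write cycle is
  bit-identical. The CSV dialect (documented header, `#` comments, header
  synonyms accepted) is an openly specified analog of vendor window tables,
  whose exact format is not public; the collision-energy column is a
  passthrough placeholder since CE ramps are instrument configuration.
- Degenerate inputs: empty filtered libraries are warnings, not crashes;
  coverage of an empty library and schemes with zero windows raise.

## Limitations

- Single-trapezoid parameterisation: charge states whose bands are
  vertically separated compete for the same staircase, so optimizing
  overall coverage can trade 3+/4+ coverage for the dominant 2+ cloud;
  designing against a charge-filtered library is the supported remedy.
- No joint optimization of coverage and cycle time, no per-retention-time
  segmentation, no fragment-level or identification-rate modelling.
- The equal-density/optimal design assumes the library is representative of
  the sample to be acquired.
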