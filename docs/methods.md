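# Methods

## Signal model

Coding DNA exhibits codon-position-dependent base composition, which
makes the base indicator tracks u_b[n] (b ∈ {A, C, G, T}) approximately
periodic with period 3. In the length-N discrete Fourier transform
U_b[k] = Σₙ u_b[n]·e^(−j2πnk/N) (unnormalised kernel, no 1/N factor)
this appears as power concentrated at k = N/3 and its mirror 2N/3.
Introns lack the codon constraint and behave like positionally
homogeneous noise. Everything in the package reduces to measuring the
prominence of that period-3 peak.

Two numeric mappings are provided. The **indicator spectrum** sums
|U_b[k]|² over the four bases; the **Z-curve spectrum** sums the squared
DFT magnitudes of the three ±1 increment tracks Δx (purine axis,
u_A−u_C+u_G−u_T), Δy (amino), Δz (weak/strong). The two differ by a
fixed linear transform of the indicator tracks and carry the same
periodicity information; whole-segment statistics use the Z-curve form,
the sliding-window track uses the indicator form. The ambiguity symbol
N maps to all-zero indicators and a (0,0,0) increment: it contributes
nothing to any spectrum but still occupies a position, so track lengths
always equal sequence length. When N is not divisible by 3 the peak
falls between bins and the nearest integer bin round(N/3) is used;
the γ-neighbourhood average R₁, R₂ over [N/3−γ, N/3+γ] and
[2N/3−γ, 2N/3+γ] absorbs the residual misalignment.

**SNR.** R = P[N/3] / Ē with Ē the mean spectral power. For a window
of length M, two identities make the per-position track O(N): at
k = M/3 the DFT kernel has period 3 in the absolute position, so the
single-bin coefficient is a cumulative-sum sliding dot product; and by
Parseval the mean power of a window's indicator spectrum equals its
count of unambiguous bases, so the local normaliser needs no transform
at all. Both identities are cross-checked in the tests against a
from-scratch FFT of individual windows.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| M (`window_length`) | 351 nt | sliding DFT window; odd so the half-width is integral, divisible by 3 so the period-3 bin M/3 is integral. Sets the boundary resolution (≈ M/2 blur) versus SNR stability trade-off. |
| T₀ (`t0`) | 2.0 | SNR decision threshold of the refinement stage; species dependent, the first coordinate the swarm searches. |
| γ (`gamma`) | 3 | smoothing half-width (positions) applied to the SNR track before thresholding; the second searched coordinate. |
| R₀ (`r0`) | 2.0 | fixed threshold of the baseline comparator. |
| segment length | 117 nt | N-equal partition span of the coarse stage (see below). |
| D (`FEATURE_DIM`) | 32 | spectral sub-bands of the segment feature vector over relative frequencies [1/4, 5/12). |
| λ, B, C | 1, 1, 1 | order-parameter dynamics; equal positive λ is the regime with the winner-take-all guarantee, and the survivor saturates at √(λ/C). |
| step, tol, max_iters | 0.1, 1e−6, 1000 | forward-Euler integration of the dynamics. |
| min exon length | 50 nt | shorter calls are dropped; short exons carry too weak a period-3 signal to call reliably. |
| merge gap | 30 nt | refined intervals closer than this merge. |
| swarm settings | 100 fish, visual 2.85, delta 9, step 1, 60 iterations | the published swarm configuration; delta is read as a companion-count crowding threshold (a crowding *fraction* mode is also available, `crowding_mode="fraction"`). |

## Design choices where the design was open

- **Segment features.** The coarse stage needs a fixed-dimension
  summary of segments of varying length. The segment's indicator power
  spectrum is *accumulated* into 32 equal sub-bands of the relative
  frequency band [1/4, 5/12) centred on 1/3, then unit-normalised.
  Binning rather than grid interpolation is load-bearing: the period-3
  peak occupies a single spectrum bin whose exact relative frequency
  depends on segment length, and a point sample on a fixed grid misses
  it almost always.
- **Prototypes and adjoints.** Class prototypes are unit-normalised
  per-class means of training features; adjoints are rows of the
  Moore–Penrose pseudo-inverse of the prototype matrix, which gives
  exact biorthogonality for linearly independent prototypes and reduces
  to the prototypes themselves when they are orthonormal.
- **Order parameters, not pattern space.** The dynamics are integrated
  in the M-dimensional order-parameter space (here M = 2 classes)
  rather than the D-dimensional pattern space; the two are equivalent
  under the standard mode reduction and the former is far cheaper. The
  fluctuation term defaults to zero (deterministic limit); optional
  seeded Gaussian noise is available for experimentation. Exact ties
  in ξ² break to the lowest class index for determinism.
- **Segment length 117 nt.** The partition span must be short enough
  that an exon at the lower end of realistic exon lengths (~120 nt) can
  dominate at least one segment; with window-length segments (351 nt) a
  120 nt exon never exceeds ~a third of any segment's content, the
  competition labels every such segment intron, and whole exons are
  lost before refinement can act. One third of the spectral window
  (still odd and divisible by 3) removes that failure mode while
  keeping segments long enough for a usable band spectrum.
- **Refinement rule set.** Smoothing (±γ moving average, shrinking at
  the track ends) precedes thresholding. Each candidate is contracted
  past sub-threshold flank positions, then extended outward while the
  adjacent position clears T₀, capped at `max_extension` per side for
  bounded runtime. If the resulting span's *mean* smoothed SNR still
  falls below T₀ — possible only when deep sub-threshold dips remain in
  the interior, i.e. the candidate bridged two exons across a weak
  stretch — the span narrows to the maximal above-threshold run around
  the candidate's SNR peak. This guarantees simultaneously that
  reported intervals have mean smoothed SNR ≥ T₀, that refinement is
  idempotent, and that the refined span shrinks monotonically as T₀
  grows.
- **Sliding-window edges.** Positions within (M−1)/2 of either end
  lack full window support and inherit the nearest supported value
  instead of fabricating spectra from truncated windows.
- **Window normaliser.** The default is the window's own mean spectral
  power (a genuinely local SNR, comparable to T₀ across positions); a
  global mode dividing by the sequence-wide average of the window means
  is available. On N-free sequence the two coincide exactly.
- **Feature-level scoring.** How a "correctly identified" exon is
  counted is a convention: here a true exon is a hit when at least half
  its bases are covered by predictions (inclusive at exactly one half),
  a true intron a correct rejection when less than half is covered; the
  fraction is the `overlap_fraction` argument. Nucleotide mode needs no
  convention and is also provided.
- **Swarm specifics.** γ is searched as a real coordinate and rounded
  at evaluation (the averaging half-width must be an integer, but fish
  moves are continuous). Prey uses 5 attempts. Behaviour order per
  fish per iteration: swarm (centroid), else follow (best companion),
  else prey; visual range and step act on raw (T₀, γ) coordinates,
  whose default bounds ([0.5, 5] × [0, 20]) give the axes comparable
  spans. All randomness flows from one seeded generator, so full
  trajectories are bit-reproducible.

## Synthetic data: what it does and does not show

The generator emulates the one property the method consumes:
codon-position-dependent composition. Exon bases at codon position c
are drawn from row c of a 3×4 stochastic matrix mixed with the uniform
distribution by the periodicity strength w ∈ [0, 1]; intron bases are
i.i.d. background; genes alternate intron/exon/…/intron. Defaults:
2–5 exons per gene configurable with 3 as the fixed default, exon
lengths uniform 120–600 nt (multiples of 3), intron lengths uniform
200–1000 nt, w = 0.9 — sizes chosen to be loosely representative of
compact vertebrate genes while keeping short, hard exons in the mix.

What passing tests on this material establish: the spectral statistics,
the competition dynamics, the refinement geometry and the optimiser
behave as designed when the period-3 signal is present at realistic
strength. What they do not establish: performance on real genomes,
where splice-site motifs, codon usage bias, GC heterogeneity, repeats
and very short exons all perturb the signal in ways the generator
deliberately omits.

## Numerical notes

- DFTs use numpy's FFT with the unnormalised e^(−j2πnk/N) kernel;
  brute-force O(N²) summation is the oracle in tests (agreement 1e−9
  relative).
- The Euler integration of the competition is stable for the default
  step 0.1 whenever Σξ² stays modest (the divergence guard trips at
  ‖ξ‖∞ > 1e6 and names the step size); the discrete update preserves
  the ordering of ξ² step by step, which is why the winner-take-all
  property survives discretisation.
- All-zero spectra (all-N input) raise an explicit undefined-SNR error
  rather than returning NaN; all-N windows inside a longer sequence get
  SNR 0.
- Problem sizes in the test suite — corpora of 5–20 genes of roughly
  2–5 kb, 10 training genes for prototypes — were chosen so the full
  suite exercises every stage end to end in well under a minute.

## Known limitations

- Single-strand only; no reverse-complement scan, no splice-site (GT–AG)
  or reading-frame consistency checks.
- Exons shorter than `min_exon_length` (50 nt) are invisible by design.
- Boundary placement inherits the ≈ M/2 blur of the sliding window;
  per-base errors concentrate within half a window of true splice
  points.
- The coarse stage can merge exons separated by introns shorter than
  about two segment lengths; the refinement fallback then keeps the
  stronger exon.
- Feature-level counts depend on the 50% coverage convention; compare
  conventions before comparing published numbers.
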