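# polytomo

Polyribosome topology from cryo-electron tomograms: synthetic tomogram
simulation, reference-free maximum-likelihood subtomogram averaging, mRNA
path tracing and circularity statistics.

## The problem

A polyribosome is a group of ribosomes threaded on one mRNA, translating it
5'→3'. Whether eukaryotic polysomes are *circular* (the mRNA forms a closed
loop, classically attributed to a cap–eIF4F–PABP–poly(A) bridge) or *linear*
can be decided from cryo-electron tomograms: subtomogram averaging recovers
each ribosome's orientation, the known positions of the mRNA entry and exit
channels on the 40S subunit then pin down where the message enters and
leaves every ribosome, and connecting exit→entry sites traces the whole
mRNA path. This package implements that computational pipeline end to end,
together with a synthetic-tomogram generator with known ground truth, so
every stage — alignment, tracing, classification, statistics — can be
validated quantitatively.

It is a library for structural-biology method developers and computational
biologists; the public face is the importable API plus the short narrative
scripts in `examples/`.

## The methods at the core

**Reference-free ML averaging.** Subvolumes `X_i` are modelled as rotated
copies of an unknown average `A` plus white Gaussian noise `σ`; orientation
is a latent variable on a discrete near-uniform SO(3) grid `{R}` and the
model is fitted by expectation–maximization,

    γ(i,R) ∝ exp( −‖X_i − T_R A‖² / 2σ² )          (E-step)
    A ← Σ_{i,R} γ(i,R) · T_R⁻¹ X_i / Σ γ,   σ² ← ⟨γ, ‖X−T_R A‖²⟩ / NV   (M-step)

starting from a subset mean of the raw particles — no external model enters
at any point. A coarse-to-fine grid (15° → 7.5° → 3.75°) keeps the search
exact and cheap; resolution is reported as the FSC = 0.5 crossing between
solvent-masked half-set averages.

**mRNA path tracing.** A link from ribosome *i* to *j* is feasible when the
exit→entry distance fits the spacer budget
`(occupancy − footprint) × 0.34 nm/nt` (occupancy = coding length per
ribosome, footprint ≈ 30 nt) and no angle along the link — between the two
ribosomes' mRNA directions or against the spacer segment itself — exceeds
120° ("no kinks"). The route is the minimum-total-spacer feasible
Hamiltonian path or tour, found by exact search (full enumeration to n = 9,
Held–Karp to n = 12), with routes whose non-adjacent spacer segments
approach closer than a quarter ribosome diameter rejected ("no knots").
A fully feasible tour means circular topology; the ordered centres then
distinguish rings, double rows, zigzags, single rows and helices. Dimers
and trimers are never assigned.

## Worked example

```bash
python examples/trace_polysome.py
```

```
candidate links: 30 ordered pairs, 9 feasible (spacer cap 37.4 nm, bend cap 120.0 deg)
solved order : p0 -> p1 -> p2 -> p3 -> p4 -> p5
closed       : True  (generated closed=True)
total spacer : 69.9 nm over 6 links
unique       : True  (best route beats runner-up by >= 5%)
topology     : circular_ring
```

A jittered hexameric ring is generated, all 30 ordered exit→entry pairs are
scored, 9 survive the spacer and bend caps, and the exact search finds a
unique closed tour — the polysome is circular. At condition scale
(`examples/condition_report.py`, 150 polysomes, true circular proportion
0.5) the recovered circular fraction is 50.0% per polysome and 49.9% per
ribosome with zero misclassifications; `examples/average_subtomograms.py`
aligns 50 particles at SNR 0.5 reference-free to a median angular error of
5.5° and a 4.7 nm FSC(0.5) resolution.

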