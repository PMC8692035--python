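# morphofit

Morphomics of the posterior rectus sheath plane (PRSP) as an implant site
for islet macroencapsulation devices.

Macroencapsulation devices for type 1 diabetes must hold a clinically
impactful number of islets while fitting a real anatomical space. The PRSP
— the potential plane between the rectus abdominis muscle belly and its
posterior fascia, bounded by the xiphoid process (cranially), the pubic
symphysis (caudally), the linea alba (medially) and the semilunar lines
(laterally) — is a thin, bilateral, well-vascularised candidate site.
`morphofit` implements the quantitative pipeline that asks: *how big a
device, of what shape, fits each patient's PRSP, and does it deliver a
therapeutic islet dose?*

It is a library first (`import morphofit`), with narrative scripts in
`examples/` and a thin `morphofit` CLI over the pipeline stages.

## The method

Starting from per-patient 3D landmark coordinates (xiphoid tip, pubis tip,
and linea-alba + left/right semilunar points at ~30 mm craniocaudal
stations):

1. **Volume construction** — each side's PRSP is the convex hull of its
   boundary points (the Delaunay tetrahedralization of a point set
   tessellates exactly its hull); its volume *V* is the enclosed volume.
2. **Sectioning** — a minimal-volume oriented bounding box is fitted; the
   hull is cut into frontal sections at 1 mm spacing perpendicular to the
   thinnest (dorsoventral) box axis.
3. **Shape optimisation** — in every convex section the maximal inscribed
   device of each shape is computed:
   - *circle*: the Chebyshev centre — max r s.t. aᵢ·c + r ≤ bᵢ over the
     edge half-planes, an exact linear program;
   - *ellipse*: max log det B s.t. ‖B aᵢ‖ + aᵢ·d ≤ bᵢ, the convex
     log-det program over the symmetric shape matrix B and centre d
     (area = π det B);
   - *rectangle*: max w·h over (centre, angle, w, h) with four-corner
     containment — a deterministic multi-start orientation search whose
     fixed-angle subproblem is solved exactly;
   - *polygon*: the largest section, reduced to ≤ 9 vertices by greedy
     least-area-loss vertex removal.
   The largest fit of each shape across the stack is that side's device.
4. **Dose model** — one IEQ is the volume of a 150 µm sphere
   (πd³/6 ≈ 1.767×10⁻³ mm³); a device of footprint area A, thickness
   0.6 mm and 10 % islet volume fraction carries
   0.10 × 0.6 × A / V_IEQ ≈ 33.95 IEQ per mm². Two devices (left + right)
   per patient are compared against the therapeutic threshold of
   10 000 IEQ kg⁻¹.
5. **Screening models** — a quadratic-kernel SVR predicts average device
   area from eight physical-exam features (age, sex, BMI, ASIS–ASIS,
   xiphoid–pubis, body depth/width/circumference); a Gaussian-kernel SVM
   classifies patients into quartile size bands. Both use 10-fold CV with
   pooled out-of-fold metrics.
6. **Cohort statistics** — Shapiro–Wilk screening, Mann–Whitney U,
   Kruskal–Wallis with Dunn's Bonferroni post hoc, Wilcoxon signed-rank
   for left/right pairs, stratified by sex, age band and WHO BMI band.

Because the original CT cohort is not public, the package ships a
synthetic-anatomy generator (`morphofit.synthetic`) whose demographics are
anchored to the published per-sex means ± SDs and whose landmark geometry
produces thin lens-like bilateral volumes. See `docs/methods.md` for the
model and its limits.

## Worked example

```sh
python examples/03_fit_devices.py
```

```
circle     area     3697 mm^2  (best in slice 8)
rectangle  area    11747 mm^2  (best in slice 4)
ellipse    area    12293 mm^2  (best in slice 5)
polygon    area    15219 mm^2  (best in slice 6)
rectangle aspect ratio: 5.08
ellipse semi-axes: 134.7 x 29.1 mm
```

One synthetic patient's left PRSP: the inscribed circle is small (a thin
tapering plane punishes isotropic shapes), the free-orientation rectangle
and the ellipse fill most of the section, and the 9-gon polygon device is
the largest but patient-specific. Running the dose model on two
12 000 mm² elliptical devices for a 70 kg patient gives
11 641 IEQ kg⁻¹ — above the 10 000 IEQ kg⁻¹ therapeutic threshold
(`examples/04_dose_model.py`).

The full pipeline with cohort summaries:

```sh
morphofit run-all --n 12 --seed 1 --out-dir results_demo
```

writes `cohort.csv`, `landmarks.csv`, `volumes.csv`, `fits.csv`,
`dose.csv`, `screening.json`, `stats.json` and a reproducibility
`manifest.json`; rerunning the same config reproduces byte-identical
CSVs.

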