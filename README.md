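# blastopol

Quantification of **asynchronous blastomere polarization** in 8-cell mouse
embryos: apical-domain detection from cortical intensity profiles,
early/late polarization timing relative to compaction, blastomere geometry,
and the division-symmetry / lineage-fate statistics that link polarization
timing to trophectoderm bias.

At the 8-cell stage each mouse blastomere assembles an *apical domain* — a
cap of polarity proteins (EZRIN, PARD6) on its contact-free surface. Most
cells polarize late, after the embryo compacts, but a minority polarize
within an hour of their third cleavage, before the inter-blastomere contact
angles reach the 120° compaction threshold. These **early-polarizing (EP)**
cells differ from **late-polarizing (LP)** cells in nuclear position, cell
shape, division symmetry and, ultimately, in their bias toward the
trophectoderm (TE) lineage. This package implements the measurement
pipeline for such data and a seeded synthetic-embryo generator that
provides ground truth for every stage.

## The core definitions

A cortical arc on a cell's contact-free cortex is an **apical domain** when

1. its length is between 33% and 80% of the total contact-free length,
2. its mean intensity is **more than 1.5×** the mean intensity of the
   remaining contact-free cortex, and
3. it is visible across **at least 3 µm** of z-depth,

with a configurable temporal persistence (default 2 frames) before an onset
is accepted. A cell is **EP** when it polarizes (1) within 60 min of the
reference cleavage (its own third cleavage for live imaging; the embryo's
last third cleavage for fixed samples) and (2) while the minimum
inter-blastomere angle (IEA) with its neighbors is still below 120°;
polarized cells failing either condition are **LP**.

Supporting quantifications: cortical enrichment
`(I_cortex − I_cyto)/I_cyto`; nuclear:cytoplasmic ratio
`INT_nucleus/INT_cyto`; IEA from circle fits to each cell's contact-free
outline (`IEA = 180° − arccos((r₁² + r₂² − d²)/(2 r₁ r₂))`); apex
angle/side:full length ratio of mid-plane cell outlines; moment-based 3-D
aspect ratios; Fisher exact and pooled two-proportion z-tests; and a
Monte-Carlo binomial goodness-of-fit test for the cell-autonomy of early
polarization.

## Worked example

```python
import numpy as np
from blastopol import SimulationConfig, ImageStack
from blastopol.synthetic import render_embryo_movie
from blastopol.pipeline import analyze_movie

cfg = SimulationConfig(noise_sd=0.0, seed=3)
movie = render_embryo_movie(cfg, np.random.default_rng(3))
stack = ImageStack(movie.data, movie.pixel_size_um, movie.z_step_um,
                   movie.frame_interval_min, movie.labels, movie.nuclei)
calls, classes = analyze_movie(
    stack, cleavage_min=dict(zip(movie.truth["cell"], movie.truth["cleavage_min"]))
)
print(classes[["cell", "onset_min", "min_iea_at_onset_deg", "class"]])
```

prints

```
   cell  onset_min  min_iea_at_onset_deg class
0     1      360.0            127.829349    LP
1     2       40.0             60.088974    EP
2     3      360.0            127.467002    LP
3     4      340.0            125.881279    LP
4     5      340.0            125.930412    LP
5     6      360.0            127.829349    LP
6     7      340.0            125.930412    LP
7     8      340.0            125.896152    LP
```

Cell 2 polarized at 40 min while its contacts were still at ~60° — an EP
cell; the others polarized after compaction (IEA ≈ 126°) and are LP. The
detected onsets equal the rendered ground-truth onset frames exactly.

The same pipeline runs from the shell:

```bash
blastopol run -o out --seed 3          # simulate → detect → classify → stats
blastopol simulate -o sim              # movie.tif + labels + lineage tables
blastopol stats --lineage sim/lineage.csv
```

## Layout

| module | contents |
|---|---|
| `blastopol.synthetic` | seeded embryo-movie renderer and lineage-table generator |
| `blastopol.profiles` | contact-free cortical profiles, enrichment/intensity ratios |
| `blastopol.detection` | three-criterion apical-domain calls, domain morphometrics |
| `blastopol.geometry` | inter-blastomere angles, apex geometry, 3-D aspect ratios |
| `blastopol.timing` | onset detection, EP/LP classification, onset histograms |
| `blastopol.stats` | symmetry/fate calls, Fisher, z-test, binomial independence |
| `blastopol.pipeline` / `blastopol.cli` | orchestration, I/O, command line |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
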