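# callosoplan

Computer-assisted trajectory planning for minimally invasive **laser
interstitial thermal therapy (LITT) anterior two-thirds corpus
callosotomy**, with simulated ablation cavities and tractography-based
quantification of the achieved interhemispheric disconnection.

Corpus callosotomy palliates drug-refractory generalised epilepsy (most
often drop attacks in Lennox–Gastaut syndrome) by sectioning the corpus
callosum, the principal commissure carrying interhemispheric seizure
spread; the splenium is spared at the first stage to limit disconnection
syndrome. Because LITT catheters are straight while the callosum is
arched, several catheters with staged pull-back ablations are needed, and
every trajectory must respect the midline vascular hazards (pericallosal
arteries on the callosal dorsum, the superior sagittal sinus). This
package is aimed at researchers studying stereotactic planning algorithms:
it implements the full planning-and-validation loop and ships a parametric
digital head phantom, so everything runs without patient data.

## Method

1. **Target generation.** From a labelled parcellation, the subcallosal
   gyrus and the anterior/middle/posterior cingulate are each dilated by
   7 mm (exact Euclidean-distance-transform dilation); adjacent pairs are
   intersected and constrained to the corpus callosum, yielding three
   disjoint target regions at the rostrum, genu and posterior body.
2. **Constrained search.** For each of five entry/target rows
   (entry gyrus, target, max skull-to-target length, max drilling angle):

   | # | entry gyrus | target | max length (mm) | max angle (°) |
   |---|-------------|--------|------|-----|
   | 1 | right superior frontal | anterior | 60 | 15 |
   | 2 | right superior parietal | middle | 110 | 35 |
   | 3 | right angular | middle | 110 | 35 |
   | 4 | left superior frontal | posterior | 90 | 35 |
   | 5 | left middle frontal | posterior | 90 | 35 |

   candidates pair scalp-surface points overlying the entry gyrus with
   target voxels, subject to hard constraints (length, drilling angle from
   the surface orthogonal, no ventricular or vessel transgression), and are
   ranked by a weighted sum of pool-normalised safety metrics.
3. **Safety metrics.** Per trajectory: intracerebral length; drilling
   angle; proportion of the catheter within the callosum; minimum vessel
   distance; and a vascular **risk score** sampled at 128 equally spaced
   nodes — piecewise linear in the node's vessel distance *d* with
   r = 0 for d ≥ 10 mm, r = (10 − d)/7 for 3 ≤ d < 10, and
   r = 1 + (3 − d)/3 for d < 3, aggregated by the maximum, so that
   **score < 1 ⟺ the whole course is > 3 mm from vasculature**.
4. **Ablation simulation.** Per selected catheter, pull-backs =
   ⌈callosal segment length / 7 mm⌉ spherical 15 mm ablations stepped
   proximally from the target form a confluent cavity, clipped to the
   callosum plus a 2 mm thermal margin.
5. **Disconnection assessment.** The cavities act as exclusion zones on
   interhemispheric streamlines; residual connectivity is the set of
   callosal voxels still traversed by surviving streamlines, reported in
   cm³ and localised along the anterior–posterior extent, with the
   callosum partitioned 2:1 into the anterior two-thirds and the spared
   splenium.

## Worked example

```bash
callosoplan run --phantom --seed 7 --out runout
```

generates the 96³ digital head phantom (parcellation, vessel tree,
5000 interhemispheric streamlines), plans all five rows, selects the final
three catheters, simulates the cavities and assesses disconnection. The
`plan_report.yaml` it writes contains (seed 7):

| role | entry gyrus | risk | min vessel dist (mm) | intracerebral (mm) | angle (°) | callosal fraction |
|------|-------------|------|------|------|------|------|
| anterior | right superior frontal | 1.11 | 2.67 | 36.2 | 13.9 | 0.68 |
| middle | right angular | 0.77 | 4.58 | 43.8 | 24.0 | 0.48 |
| posterior | left middle frontal | 0.76 | 4.65 | 44.0 | 21.9 | 0.48 |

with pull-backs `[4, 3, 3]` over callosal segments of 24.3/20.9/21.0 mm and
a combined cavity of 6.2 cm³. The disconnection summary reports 634 of
5000 streamlines surviving, residual connectivity 0.221 cm³ confined to
the spared splenium, and **0.000 cm³ residual in the anterior two-thirds**
(total callosum 4.28 cm³ = 3.17 anterior + 1.11 splenium). The anterior
catheter descends the genu limb through a 2.7 mm paramedian corridor —
the lateral shift forced by the pericallosal arteries — while the risk
score 1.11 records that its corridor is narrower than 3 mm.

The adversarial variant (`--adversarial`) adds a cortical vascular wall
over the right frontal approach: row 1 becomes infeasible and the report
localises residual anterior connectivity at the anterior-most callosum,
the known failure mode of the three-catheter technique.

## Layout

- `src/callosoplan/volio.py` — NIfTI/TCK/report I/O, coordinate authority
- `src/callosoplan/phantom.py` — digital head phantom, vessels, streamlines
- `src/callosoplan/targetgen.py` — dilation-and-overlap target regions
- `src/callosoplan/riskmetrics.py` — per-trajectory safety metrics
- `src/callosoplan/planner.py` — constrained search and plan selection
- `src/callosoplan/ablation.py` — pull-back cavity simulation
- `src/callosoplan/disconnection.py` — streamline filtering and residuals
- `src/callosoplan/cli.py` — `callosoplan` command-line pipeline
- `docs/methods.md` — model assumptions, parameters, limitations
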