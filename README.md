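# chromoscore

Quantitative scoring of dye concentration for chromoendoscopy.

During chromoendoscopy a vital or contrast dye (methylene blue, indigo
carmine) is applied to the gastric mucosa to make early lesions and the
mucosal surface pattern easier to see. Too little dye changes nothing; too
much floods the surface and washes the pattern out. Somewhere in between
lies an optimal concentration, and it differs by stain and by anatomical
region (fundus vs. pylorus). `chromoscore` implements two image scores
that make "easier to see" measurable, and a pipeline that applies them
across a staining-concentration series to locate the optimum. It is aimed
at groups optimizing staining protocols for capsule or conventional
endoscopy who work from patch photographs of stained tissue.

## The two scores

**Lesion-to-background contrast.** With a lesion region R_l and a healthy
reference region R_h annotated on the grayscale image, the contrast score
is the difference of their mean gray values:

    I_c = g(R_l) - g(R_h)

On an 8-bit scale |I_c| lies in [0, 255]; larger means a more conspicuous
lesion. Contrast stains such as indigo carmine, which pool in depressed
lesions, are evaluated with this score.

**Global texture variance.** Around each pixel (c_x, c_y), N intensities
are sampled on a circle of radius R at angles 2πi/N (the local-binary-
pattern neighborhood; off-grid samples are bilinearly interpolated), and
their population variance is taken:

    var(R,N)(c_x, c_y) = (1/N) Σ_i (p_n(i) − μ)²,   μ = (1/N) Σ_i p_n(i)

Averaging this over every pixel whose sampling circle fits inside the
image gives the image-level score var(R,N)_g, and averaging *that* over
radii R = 10, 20, 30, 40, 50 px captures texture at several spatial
frequencies. Absorptive stains such as methylene blue, which enhance the
overall mucosal pattern rather than one lesion, are evaluated with this
score.

The pipeline averages per-concentration replicate scores, takes the grid
argmax as the optimal concentration, and reports the percent increase of
the optimal score over the unstained baseline.

Because the original stained-patch photographs are not publicly
deposited, the package ships a synthetic-data generator that renders
stained-mucosa patches (correlated texture field + planted elliptical
lesion + noise) whose dose-response is unimodal with a configurable
planted optimum, so the whole pipeline can be exercised and validated
end to end.

## Worked example

Generate the full synthetic two-stain design (190 patches: 90 indigo
carmine with planted lesions, 100 methylene blue without) and analyze it:

```python
from chromoscore import ExperimentDesign, generate_design, score_records

design = ExperimentDesign.full_printed()
records = generate_design(design, master_seed=1)
table, summaries = score_records(records, design)
for (stain, region), s in sorted(summaries.items()):
    print(
        f"{stain}/{region}: optimum {s.optimal_concentration}% "
        f"({s.score_type} score {s.optimal_mean_score:.2f}, "
        f"+{s.percent_increase:.0f}% over unstained)"
    )
```

prints

```text
indigo_carmine/fundus: optimum 0.2% (contrast score 58.52, +513% over unstained)
indigo_carmine/pylorus: optimum 0.6% (contrast score 58.61, +600% over unstained)
methylene_blue/fundus: optimum 0.4% (texture score 334.43, +296% over unstained)
methylene_blue/pylorus: optimum 0.4% (texture score 336.83, +295% over unstained)
```

Each line is one (stain, region) arm of the experiment: the concentration
whose mean score over five replicate patches is highest, that mean score
(gray levels for contrast, squared gray levels for texture variance), and
how much staining at the optimum improved the score relative to the
unstained patches. The generator planted its optima at 0.2% / 0.6%
(indigo, fundus / pylorus) and 0.4% (methylene blue); the pipeline
recovers all four from the images alone, including the region dependence
of the contrast-stain optimum.

The same run is available from the shell:

```sh
chromoscore all --design full --seed 1 --out results/run1
```

which writes the images, annotation JSONs, manifest, long-format score
table, JSON summary and a per-concentration score plot.

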