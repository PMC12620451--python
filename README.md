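# cropnpp

Crop net primary productivity (NPP) from multispectral imagery and
monthly meteorology, via the CASA light-use-efficiency model with a
CNN-based FPAR retrieval.

## The problem

NPP — the organic carbon fixed by vegetation per unit area and time —
is the central quantity for assessing cropland productivity and carbon
sink capacity, but field measurement (harvest, oven-drying, carbon
assay) does not scale. The CASA model estimates NPP from remote
sensing as

    NPP(x,t) = APAR(x,t) · ε(x,t),      APAR = SOL · FPAR · 0.5,
    ε = Tε1 · Tε2 · Wε · ε_max

where FPAR is the fraction of photosynthetically active radiation
absorbed by the canopy, SOL the monthly solar radiation (MJ/m²/month),
and ε the light-use efficiency (gC/MJ), down-regulated from its maximum
ε_max (0.389 gC/MJ for crops) by temperature and water stress.

FPAR is the lever: the classic CASA derives it from linear stretches of
NDVI and the simple ratio (RVI), which saturate over dense canopies.
`cropnpp` instead computes 15 vegetation indices from the band stack,
ranks them by recursive feature elimination, and regresses FPAR with a
small 1-D convolutional network (3 conv layers of 16/32/64 filters,
kernel 2, dropout 0.3, Adam lr 0.001, MSE, 10 epochs, 7:3 split). The
empirical NDVI/RVI FPAR is retained as a built-in baseline so both
routes can be compared through the same CASA core.

Because imagery and field plots of the kind this method targets are not
bundled, the package includes a first-class synthetic scene generator
(double-logistic LAI seasons, Beer–Lambert FPAR, endmember-mixture
reflectance with band noise, sinusoidal meteorology, optional cloud
patches) whose true NPP is the CASA forward model — every stage is
testable end to end, offline.

Audience: agro-ecosystem modellers and remote-sensing practitioners who
want a transparent, fully scripted CASA pipeline with a modern FPAR
retrieval and a rigorous self-verifying test bed.

## Worked example

Run the full pipeline on the default synthetic scene (40×40 pixels,
April–October season, 2756 training samples):

```bash
cropnpp run --seed 1 --out runs/demo
```

This prints the per-stage metrics (also written to
`runs/demo/manifest.json`):

```
"fpar_cnn":       {"rmse": 0.0344, "mae": 0.0280, "r2": 0.9908, "n": 11200}
"fpar_empirical": {"rmse": 0.1048, "mae": 0.0813, "r2": 0.9143, "n": 11200}
"npp_mape_cnn": 3.21
"npp_mape_empirical": 12.20
```

Reading: across the 11,200 valid pixel-months, the CNN retrieval
reconstructs the scene's true FPAR with RMSE 0.034 versus 0.105 for the
classic NDVI/RVI stretch, and the resulting growing-season NPP deviates
from truth by 3.2% (MAPE) versus 12.2% for the empirical route. The
mean annual crop NPP on this scene is ≈429 gC/m²/yr. Monthly and annual
NPP rasters plus a per-class zonal CSV land in `runs/demo/`.

The individual stages are also exposed as subcommands —
`simulate`, `indices`, `meteo`, `fpar-train`, `fpar-predict`, `npp`,
`evaluate` — all reading/writing multiband TIFF (georeference in the
image description tag) and CSV, so real analysis-ready rasters and
synthetic fixtures are interchangeable. The same functionality is
available as a library (`cropnpp.run_pipeline`, `cropnpp.compute_all`,
`cropnpp.train_cnn`, `cropnpp.run_casa`, ...).

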