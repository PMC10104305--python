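# File schemas

All tables are UTF-8 comma-separated CSV with a mandatory header row and
"." decimal mark. Numeric columns carry unit suffixes.

## palms.csv — destructive-sample records

| column | type | description |
|---|---|---|
| palm_id | str | unique individual id |
| class_label | str | petiole-diameter sampling class |
| D_cm | float | stem base diameter, cm |
| MDp_cm | float | mean petiole diameter, cm (= SDp_cm / Npf) |
| SDp_cm | float | sum of petiole diameters, cm |
| H_m | float | total height, base to tallest frond, m |
| Npf | int | live frond count (≥ 3) |
| TD_g_cm3 | float | mean tissue density, g cm⁻³ |
| stem_kg, sheath_kg, petiole_kg, rachis_kg, leaflet_kg | float | component dry masses, kg |
| agb_kg | float | total AGB, kg (must equal the component sum) |

## samples.csv — lab samples

| column | type | description |
|---|---|---|
| palm_id | str | individual the sample came from |
| component | str | one of stem, sheath, petiole, rachis, leaflet |
| fresh_g | float | fresh mass, g |
| dry_g | float | oven-dry mass, g (≤ fresh_g) |
| volume_cm3 | float/empty | displaced volume, cm³; empty for leaflet |

## inventory.csv — one plot's stems

One plot per file; `plot_id` and `area_ha` are constant columns.

| column | type | description |
|---|---|---|
| plot_id | str | plot label |
| area_ha | float | plot area, hectares |
| kind | str | "tree" or "palm" |
| stem_id | str | stem label |
| D_cm | float | tree DBH, cm (trees only; rows with D < 10 are dropped with a warning) |
| wood_density_g_cm3 | float | tree wood density (trees only) |
| H_m | float | height, m (required for trees, optional for palms) |
| Npf | int | frond count (palms; required) |
| SDp_cm, TD_g_cm3 | float/empty | optional palm predictors |

## published_models.csv — packaged coefficient fixture

One row per published model (m1–m22): `model_id`, `predictors`
("+"-joined, canonical symbols), intercept `a`, slopes `b`, `c`, `d`
(empty when unused), `R2adj`, `RSE`, `AIC`, `RMSE`, `BiasPct`, `CF`,
`subset` (mean-petiole-diameter range), `n`, and the best-single /
best-multiple flags. The loader verifies a SHA-256 checksum and the
identity CF = exp(RSE²/2) to within two-decimal rounding.
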