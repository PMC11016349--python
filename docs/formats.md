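# File formats

All interchange formats are plain text and versioned.

## Plan XML (schema v1)

One `<controlPoint>` per motion step, carrying **absolute** axis values
(reference + delta), the gantry angle, the MU to deliver at that position,
and the imaging directive.  Floats are serialized in shortest round-trip
(`repr`) form, so render → parse → render is byte-identical.

```xml
<?xml version='1.0' encoding='utf-8'?>
<dynqaPlan schemaVersion="1">
  <meta key="coordinate_system" value="IEC61217" />
  <meta key="label" value="sgrt-dynqa monthly" />
  <meta key="rotation_sequencing" value="absolute-offsets;return-to-zero-between-axes;monotone-sweep" />
  <reference lat_mm="0.0" lng_mm="0.0" vrt_mm="0.0" yaw_deg="0.0" pitch_deg="0.0" roll_deg="0.0" />
  <sequence>
    <controlPoint index="0" gantry_deg="0.0" acquireMv="true" mu="0.0">
      <couch lat_mm="0.0" lng_mm="0.0" vrt_mm="0.0" yaw_deg="0.0" pitch_deg="0.0" roll_deg="0.0" />
    </controlPoint>
    <controlPoint index="1" gantry_deg="0.0" acquireMv="true" mu="50.0">
      <couch lat_mm="-50.0" lng_mm="0.0" vrt_mm="0.0" yaw_deg="0.0" pitch_deg="0.0" roll_deg="0.0" />
    </controlPoint>
  </sequence>
</dynqaPlan>
```

Axis signs follow IEC 61217: lat = X, lng = Y, vrt = Z (+up); yaw/pitch/roll
about Z/X/Y in degrees, normalized to (−180, 180].

## Trajectory log (`sgrt-dynqa-trajlog` dialect v1)

Header block of `# key: value` lines, then CSV.  Uniform time grid at the
declared sample interval; `mu` is cumulative and non-decreasing; every couch
axis and the gantry appear as `_expected`/`_actual` pairs.  Values carry six
decimal places (round-trips are exact to 1e−6); unknown extra columns are
preserved.  Vendor binary trajectory logs must be converted externally.

```
# dialect: sgrt-dynqa-trajlog
# version: 1
# sample_interval_s: 0.02
t,lat_mm_expected,lat_mm_actual,...,gantry_deg_expected,gantry_deg_actual,mu
0.000000,0.000000,0.000000,...,0.000000,0.000000,0.000000
0.020000,0.000000,0.000000,...,0.000000,0.000000,0.000000
```

## Surface log (`sgrt-dynqa-surflog` dialect v1)

Same layout; timestamps may be irregular; exactly the six offset columns
(the ROI's 6-DoF offset from the reference capture).  The dialect has **no
beam-on flag**; a beam-like column is dropped with a warning.

```
# dialect: sgrt-dynqa-surflog
# version: 1
t,lat_mm,lng_mm,vrt_mm,yaw_deg,pitch_deg,roll_deg
0.000000,0.012000,-0.031000,0.004000,0.010000,-0.020000,0.000000
0.066667,0.020000,-0.015000,0.001000,0.030000,-0.010000,0.010000
```

## MV images

16-bit PNG (or TIFF) plus a JSON sidecar `<stem>.json` with
`pixel_pitch_mm`, `sid_mm`, `sad_mm`, `gantry_deg`, `step_index`; or DICOM,
where `RTImageSID`, `RadiationMachineSAD`, `ImagePlanePixelSpacing` and
`GantryAngle` take precedence.

## Report JSON (schema v1)

`generate_report(qa, "json")` emits a versioned document with tolerances,
per-record expected/measured values per source, signed extreme deviations,
and verdicts; `load_report_json` is its lossless inverse.
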