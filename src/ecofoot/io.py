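"""Readers and writers: TSV account matrices, GeoTIFF rasters, YAML config.

Matrix files are tab-delimited UTF-8 with explicit two-row axis headers
(region, then sector) mirroring common MRIO distribution layouts without
binding to any vendor format.  All writers are inverses of their readers on
valid data.  Rasters are single-band GeoTIFFs; the country mask carries its
region list in a JSON sidecar (``<mask>.regions.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .characterization import (
    CountryMaskSet,
    GeoTransform,
    MappingEntry,
    PressureMapping,
    RasterLayer,
)
from .errors import AlignmentError, ParseError, StructuralError, UnitError
from .footprint import AttributionTable, FootprintTensor, GroupTransferTable
from .mrio import MRIOAccounts, RegionSectorIndex, SatelliteAccount

FORMAT_VERSION = "1"

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_NODATA = 42113


# ---------------------------------------------------------------------------
# delimited matrices


def _check_duplicate_pairs(path: Path, n_header: int, n_index: int) -> None:
    with open(path, encoding="utf-8") as fh:
        header = [fh.readline().rstrip("\n").split("\t") for _ in range(n_header)]
    cols = list(zip(*(h[n_index:] for h in header)))
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate column label(s) {sorted(dupes)}")


def _pairs_frame(values: np.ndarray, index: RegionSectorIndex) -> pd.DataFrame:
    mi = pd.MultiIndex.from_tuples(index.pairs, names=["region", "sector"])
    return pd.DataFrame(values, index=mi, columns=mi)


def write_accounts(
    out_dir: str | Path, accounts: MRIOAccounts, satellite: SatelliteAccount
) -> dict[str, str]:
    """Write Z, x, Y and the satellite as TSV; returns role → filename."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = accounts.index
    mi = pd.MultiIndex.from_tuples(idx.pairs, names=["region", "sector"])

    _pairs_frame(accounts.Z, idx).to_csv(out / "transactions.tsv", sep="\t")
    pd.DataFrame({"output": accounts.x}, index=mi).to_csv(out / "output.tsv", sep="\t")
    pd.DataFrame(accounts.Y, index=mi, columns=list(idx.regions)).to_csv(
        out / "final_demand.tsv", sep="\t"
    )
    smi = pd.MultiIndex.from_tuples(
        list(zip(satellite.labels, satellite.units)), names=["pressure", "unit"]
    )
    pd.DataFrame(satellite.F, index=smi, columns=mi).to_csv(
        out / "satellite.tsv", sep="\t"
    )
    return {
        "transactions": "transactions.tsv",
        "output": "output.tsv",
        "final_demand": "final_demand.tsv",
        "satellite": "satellite.tsv",
    }


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_accounts(manifest: "BundleManifest") -> tuple[MRIOAccounts, SatelliteAccount]:
    """Load labelled, dimension-checked accounts from a bundle manifest.

    Row and column label order of the transaction matrix defines the
    region-sector index.
    """
    base = manifest.base_dir
    zp = base / manifest.paths["transactions"]
    _check_duplicate_pairs(zp, n_header=2, n_index=1)
    zdf = _read_tsv(zp, header=[0, 1], index_col=[0, 1])

    rows = list(zdf.index)
    regions: list[str] = []
    sectors: list[str] = []
    for r, sec in rows:
        if r not in regions:
            regions.append(str(r))
    k = len(rows) // len(regions)
    sectors = [str(sec) for _, sec in rows[:k]]
    index = RegionSectorIndex(regions=regions, sectors=sectors)
    if list(index.pairs) != [(str(r), str(s)) for r, s in rows]:
        raise ParseError(f"{zp}: rows are not contiguous region blocks of sectors")

    xdf = _read_tsv(base / manifest.paths["output"], index_col=[0, 1])
    ydf = _read_tsv(base / manifest.paths["final_demand"], index_col=[0, 1])
    accounts = MRIOAccounts(
        index=index,
        Z=zdf.to_numpy(dtype=float),
        x=xdf["output"].to_numpy(dtype=float),
        Y=ydf.to_numpy(dtype=float),
    )
    sp = base / manifest.paths["satellite"]
    sdf = _read_tsv(sp, header=[0, 1], index_col=[0, 1])
    labels = tuple(str(lab) for lab, _ in sdf.index)
    units = tuple(str(u) for _, u in sdf.index)
    try:
        satellite = SatelliteAccount(
            index=index, labels=labels, F=sdf.to_numpy(dtype=float), units=units
        )
    except (StructuralError, UnitError) as exc:
        raise ParseError(f"{sp}: {exc}") from exc
    return accounts, satellite


# ---------------------------------------------------------------------------
# rasters


def write_raster(path: str | Path, layer: RasterLayer) -> None:
    """Write a single-band float GeoTIFF with georeference and nodata tags."""
    tf = layer.transform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(tf.dx), float(tf.dy), 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(tf.x_origin), float(tf.y_origin), 0.0),
        ),
        # minimal GeoKey directory: geographic model
        (_TAG_GEO_KEYS, "H", 8, (1, 1, 0, 1, 1024, 0, 1, 2)),
    ]
    if layer.nodata is not None:
        extratags.append((_TAG_NODATA, "s", 0, str(layer.nodata)))
    tifffile.imwrite(str(path), layer.values.astype(np.float64), extratags=extratags)


def write_mask(path: str | Path, masks: CountryMaskSet) -> None:
    tf = masks.transform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(tf.dx), float(tf.dy), 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(tf.x_origin), float(tf.y_origin), 0.0),
        ),
    ]
    tifffile.imwrite(str(path), masks.mask.astype(np.int32), extratags=extratags)
    sidecar = Path(str(path) + ".regions.json")
    sidecar.write_text(json.dumps(list(masks.regions)), encoding="utf-8")


def _read_tags(path: Path) -> tuple[np.ndarray, GeoTransform, float | None]:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        transform = GeoTransform()
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        if scale is not None and tie is not None:
            dx, dy = float(scale.value[0]), float(scale.value[1])
            x0, y0 = float(tie.value[3]), float(tie.value[4])
            transform = GeoTransform(x_origin=x0, y_origin=y0, dx=dx, dy=dy)
        nd_tag = page.tags.get(_TAG_NODATA)
        nodata = float(nd_tag.value) if nd_tag is not None else None
    return values, transform, nodata


def read_raster(path: str | Path) -> RasterLayer:
    values, transform, nodata = _read_tags(Path(path))
    return RasterLayer(values=values, transform=transform, nodata=nodata)


def read_mask(path: str | Path) -> CountryMaskSet:
    values, transform, _ = _read_tags(Path(path))
    sidecar = Path(str(path) + ".regions.json")
    if not sidecar.exists():
        raise ParseError(f"missing region sidecar {sidecar}")
    regions = json.loads(sidecar.read_text(encoding="utf-8"))
    return CountryMaskSet(
        mask=values.astype(np.int64), regions=tuple(regions), transform=transform
    )


def read_raster_stack(
    paths: Mapping[str, str | Path], mask_path: str | Path
) -> tuple[dict[str, RasterLayer], CountryMaskSet]:
    """Load a set of co-registered rasters plus the country mask.

    Grid shape and geotransform equality is enforced across the whole
    stack; a mismatch names the offending file.
    """
    masks = read_mask(mask_path)
    ref_shape, ref_tf = masks.mask.shape, masks.transform
    layers: dict[str, RasterLayer] = {}
    for name, p in paths.items():
        layer = read_raster(p)
        if layer.shape != ref_shape or layer.transform != ref_tf:
            raise AlignmentError(
                f"{p}: grid {layer.shape}/{layer.transform} does not match "
                f"mask {ref_shape}/{ref_tf}"
            )
        layers[name] = layer
    return layers, masks


# ---------------------------------------------------------------------------
# config: mapping, grouping


def write_mapping(path: str | Path, mapping: PressureMapping) -> None:
    entries = [
        {
            "satellite_label": e.pressure,
            "pathway": e.pathway,
            "unit_in": e.unit_in,
            "unit_out": e.unit_out,
            "conversion": e.conversion,
            "spatial_flag": e.spatial,
        }
        for e in mapping.entries
    ]
    Path(path).write_text(
        yaml.safe_dump({"entries": entries}, sort_keys=False), encoding="utf-8"
    )


def read_mapping(path: str | Path) -> PressureMapping:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        entries = tuple(
            MappingEntry(
                pressure=str(e["satellite_label"]),
                pathway=str(e["pathway"]),
                unit_in=str(e["unit_in"]),
                unit_out=str(e["unit_out"]),
                conversion=float(e["conversion"]),
                spatial=bool(e["spatial_flag"]),
            )
            for e in raw["entries"]
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed mapping entry ({exc})") from exc
    return PressureMapping(entries=entries)


def write_grouping(path: str | Path, grouping: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region\tgroup\n")
        for region in grouping:
            fh.write(f"{region}\t{grouping[region]}\n")


def read_grouping(path: str | Path) -> dict[str, str]:
    df = _read_tsv(Path(path))
    if list(df.columns) != ["region", "group"]:
        raise ParseError(f"{path}: expected columns region, group")
    return dict(zip(df["region"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# bundle manifest


@dataclass
class BundleManifest:
    """Paths (relative to ``base_dir``) of one input bundle, by role."""

    base_dir: Path
    paths: dict[str, str]
    version: str = FORMAT_VERSION
    seed: int | None = None

    def __post_init__(self) -> None:
        self.base_dir = Path(self.base_dir)
        if self.version != FORMAT_VERSION:
            raise ParseError(f"unrecognized bundle format version {self.version!r}")
        missing = [
            p for p in self.paths.values() if not (self.base_dir / p).exists()
        ]
        if missing:
            raise ParseError(f"bundle references missing file(s): {missing}")

    def save(self) -> Path:
        path = self.base_dir / "manifest.json"
        payload = {"version": self.version, "seed": self.seed, "paths": self.paths}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
        return path


def read_manifest(path: str | Path) -> BundleManifest:
    path = Path(path)
    raw = json.loads(path.read_text(encoding="utf-8"))
    return BundleManifest(
        base_dir=path.parent,
        paths=dict(raw["paths"]),
        version=str(raw.get("version", "")),
        seed=raw.get("seed"),
    )


def write_bundle(
    out_dir: str | Path,
    accounts: MRIOAccounts,
    satellite: SatelliteAccount,
    mapping: PressureMapping,
    world=None,
    grouping: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> BundleManifest:
    """Write a complete input bundle (accounts, config, optional rasters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_accounts(out, accounts, satellite)
    write_mapping(out / "mapping.yaml", mapping)
    paths["mapping"] = "mapping.yaml"
    if grouping is not None:
        write_grouping(out / "grouping.tsv", grouping)
        paths["grouping"] = "grouping.tsv"
    if world is not None:
        rasters = out / "rasters"
        rasters.mkdir(exist_ok=True)
        write_mask(rasters / "country_mask.tif", world.masks)
        paths["country_mask"] = "rasters/country_mask.tif"
        for lab in sorted(world.factor_layers):
            slug = lab.replace(" ", "_")
            write_raster(rasters / f"cf_{slug}.tif", world.factor_layers[lab])
            write_raster(rasters / f"pressure_{slug}.tif", world.pressure_layers[lab])
            paths[f"cf:{lab}"] = f"rasters/cf_{slug}.tif"
            paths[f"pressure:{lab}"] = f"rasters/pressure_{slug}.tif"
    manifest = BundleManifest(base_dir=out, paths=paths, seed=seed)
    manifest.save()
    return manifest


def read_world(manifest: BundleManifest):
    """Reassemble raster layers + mask from a bundle, or None if absent."""
    from .synthetic import SyntheticWorld

    if "country_mask" not in manifest.paths:
        return None
    cf_roles = {
        role[3:]: p for role, p in manifest.paths.items() if role.startswith("cf:")
    }
    pr_roles = {
        role[9:]: p
        for role, p in manifest.paths.items()
        if role.startswith("pressure:")
    }
    base = manifest.base_dir
    factor_layers, masks = read_raster_stack(
        {lab: base / p for lab, p in cf_roles.items()},
        base / manifest.paths["country_mask"],
    )
    pressure_layers, _ = read_raster_stack(
        {lab: base / p for lab, p in pr_roles.items()},
        base / manifest.paths["country_mask"],
    )
    return SyntheticWorld(
        masks=masks,
        factor_layers=factor_layers,
        pressure_layers=pressure_layers,
        hotspots=(),
    )


# ---------------------------------------------------------------------------
# results


def _write_with_unit(path: Path, df: pd.DataFrame, unit: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit: {unit}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() or c in "_-" else "_" for c in label.strip())


def write_results(
    out_dir: str | Path,
    footprints: Sequence[FootprintTensor] = (),
    attributions: Sequence[AttributionTable] = (),
    transfers: Sequence[GroupTransferTable] = (),
    scores: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write result tables as TSV with a unit header line and a results manifest.

    Column order is deterministic (region order of the inputs); re-running
    with identical inputs produces byte-identical numeric content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for fp in footprints:
        name = f"{fp.kind}_footprint.tsv"
        df = pd.DataFrame(
            fp.aggregate,
            index=pd.Index(fp.labels, name="pressure"),
            columns=list(fp.index.regions),
        )
        df.insert(0, "unit", list(fp.units))
        _write_with_unit(out / name, df, "per row, see unit column")
        files[name] = fp.kind
    for attr in attributions:
        name = f"attribution_{_slug(attr.pressure)}__{_slug(attr.unit)}.tsv"
        df = pd.DataFrame(
            attr.table,
            index=pd.Index(attr.regions, name="origin"),
            columns=list(attr.regions),
        )
        _write_with_unit(out / name, df, attr.unit)
        files[name] = f"attribution:{attr.pressure}"
    for tr in transfers:
        for form in ("absolute", "column_percent"):
            name = f"transfers_{_slug(tr.grouping_label)}_{form}.tsv"
            values = getattr(tr, form)
            df = pd.DataFrame(
                values,
                index=pd.Index(tr.groups, name="origin_group"),
                columns=list(tr.groups),
            )
            _write_with_unit(
                out / name, df, tr.unit if form == "absolute" else "percent of column"
            )
            files[name] = f"transfers:{tr.grouping_label}:{form}"
    if scores is not None:
        name = "comparison.tsv"
        _write_with_unit(out / name, scores, "standard scores (dimensionless)")
        files[name] = "comparison"
    (out / "results_manifest.json").write_text(
        json.dumps(files, indent=2, sort_keys=True), encoding="utf-8"
    )
    return files


def read_attribution(path: str | Path) -> AttributionTable:
    """Round-trip reader for an attribution table written by write_results."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    unit = first.removeprefix("# unit: ").strip()
    df = pd.read_csv(
        path, sep="\t", skiprows=1, index_col=0, float_precision="round_trip"
    )
    pressure = path.stem.removeprefix("attribution_").split("__")[0]
    return AttributionTable(
        pressure=pressure,
        regions=tuple(str(c) for c in df.columns),
        table=df.to_numpy(dtype=float),
        unit=unit,
    )
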