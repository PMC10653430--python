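#!/usr/bin/env python
"""Download the public BiGG models used by the benchmarks (needs network).

Files are written to src/optenvelope/data/ so that benchmarks and the
acceptance report can find them offline afterwards.
"""

import sys
import urllib.request
from pathlib import Path

MODELS = ["iJR904", "iMM904"]
BASE = "http://bigg.ucsd.edu/static/models/{}.json"


def main() -> int:
    outdir = Path(__file__).resolve().parents[1] / "src" / "optenvelope" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    status = 0
    for name in MODELS:
        dest = outdir / f"{name}.json"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = BASE.format(name)
        try:
            print(f"fetching {url} ...")
            urllib.request.urlretrieve(url, dest)
            print(f"wrote {dest} ({dest.stat().st_size} bytes)")
        except OSError as exc:
            print(f"failed to fetch {name}: {exc}", file=sys.stderr)
            status = 1
    return status


if __name__ == "__main__":
    raise SystemExit(main())
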