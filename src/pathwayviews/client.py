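"""Cancellable WikiPathways REST client.

The transport layer is pluggable: anything with a ``request(url)``
method returning a response exposing ``status``, ``read_chunk(timeout)``
and ``close()`` will do, which keeps the client fully testable without
a network.  The default transport uses the standard library.

Cancellation contract: every operation takes an optional
``CancellationToken``.  A token that is already set causes the
operation to return cancelled without any network call; a token set
mid-transfer aborts the underlying request within one polling interval
and never surfaces partial results — the response body is discarded and
the on-disk cache is written only after a complete transfer, via an
atomic rename.
"""

from __future__ import annotations

import json
import logging
import re
import socket
import threading
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayRef",
    "CancellationToken",
    "ClientConfig",
    "load_config",
    "WikiPathwaysClient",
    "OperationCancelled",
    "TransportError",
    "ServiceError",
    "NotFoundError",
]

WPID_PATTERN = re.compile(r"^WP\d+$")

DEFAULT_BASE_URL = "https://webservice.wikipathways.org"


class OperationCancelled(Exception):
    """The operation stopped because its token was set; no results exist."""


class TransportError(IOError):
    """Network-level failure (DNS, refused connection, reset, ...)."""


class ServiceError(IOError):
    """HTTP failure from the service; carries the status code."""

    def __init__(self, status: int, message: str = "") -> None:
        super().__init__(message or f"service returned HTTP {status}")
        self.status = status


class NotFoundError(ServiceError):
    """The requested pathway does not exist."""

    def __init__(self, what: str) -> None:
        super().__init__(404, f"not found: {what}")


@dataclass(frozen=True)
class PathwayRef:
    """One search hit: a pathway's stable id plus display metadata."""

    wpid: str
    name: str = ""
    organism: str = ""
    revision: str = ""

    def __post_init__(self) -> None:
        if not WPID_PATTERN.match(self.wpid):
            raise ValueError(f"invalid WikiPathways id {self.wpid!r} (expected WP<digits>)")


class CancellationToken:
    """Observable, sticky cancellation flag.

    Settable from any thread; once set it stays set.
    """

    def __init__(self) -> None:
        self._event = threading.Event()

    def cancel(self) -> None:
        self._event.set()

    @property
    def cancelled(self) -> bool:
        return self._event.is_set()

    def wait(self, timeout: float) -> bool:
        return self._event.wait(timeout)


@dataclass
class ClientConfig:
    base_url: str = DEFAULT_BASE_URL
    timeout_seconds: float = 30.0
    cache_dir: Optional[Path] = None
    poll_interval: float = 0.05  # cancellation latency bound per chunk


def load_config(path: Union[str, Path]) -> ClientConfig:
    """Read a ``key=value`` config file ('#' comments allowed)."""
    cfg = ClientConfig()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {ln} is not key=value: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "base_url":
            cfg.base_url = value
        elif key == "timeout_seconds":
            cfg.timeout_seconds = float(value)
        elif key == "cache_dir":
            cfg.cache_dir = Path(value)
        elif key == "poll_interval":
            cfg.poll_interval = float(value)
        else:
            logger.warning("unknown config key %r ignored", key)
    return cfg


class UrllibTransport:
    """Default transport on the standard library's HTTP machinery.

    Reads in 8 KiB chunks so the client can observe its token between
    chunks; each read is bounded by the configured socket timeout.
    """

    def __init__(self, timeout_seconds: float = 30.0) -> None:
        self.timeout_seconds = timeout_seconds

    def request(self, url: str) -> "UrllibResponse":
        try:
            resp = urllib.request.urlopen(url, timeout=self.timeout_seconds)
        except urllib.error.HTTPError as e:
            return UrllibResponse(e, status=e.code)
        except (urllib.error.URLError, socket.timeout, OSError) as e:
            raise TransportError(str(e)) from e
        return UrllibResponse(resp, status=resp.status)


class UrllibResponse:
    def __init__(self, resp, status: int) -> None:
        self._resp = resp
        self.status = status

    def read_chunk(self, timeout: float) -> Optional[bytes]:
        """Next chunk of the body; b'' at EOF, None when no data arrived
        within the window."""
        try:
            return self._resp.read(8192)
        except socket.timeout:
            return None

    def close(self) -> None:
        try:
            self._resp.close()
        except Exception:
            pass


class WikiPathwaysClient:
    """Search and download pathways; every operation honors its token."""

    def __init__(self, config: Optional[ClientConfig] = None, transport=None) -> None:
        self.config = config or ClientConfig()
        self.transport = transport or UrllibTransport(self.config.timeout_seconds)

    # -- low level ---------------------------------------------------------
    def _fetch(self, url: str, token: Optional[CancellationToken]) -> bytes:
        if token is not None and token.cancelled:
            raise OperationCancelled("cancelled before request started")
        try:
            resp = self.transport.request(url)
        except TransportError:
            raise
        except (OSError, urllib.error.URLError) as e:
            raise TransportError(str(e)) from e
        try:
            if resp.status == 404:
                raise NotFoundError(url)
            if resp.status >= 400:
                raise ServiceError(resp.status)
            chunks: list[bytes] = []
            while True:
                if token is not None and token.cancelled:
                    raise OperationCancelled("cancelled mid-transfer")
                chunk = resp.read_chunk(self.config.poll_interval)
                if chunk is None:
                    continue
                if chunk == b"":
                    break
                chunks.append(chunk)
            return b"".join(chunks)
        finally:
            resp.close()

    # -- operations --------------------------------------------------------
    def find_pathways(
        self,
        query: str,
        organism: Optional[str] = None,
        token: Optional[CancellationToken] = None,
    ) -> list[PathwayRef]:
        """Full-text pathway search; empty list on no hits.

        Raises OperationCancelled / TransportError / ServiceError as
        distinguishable failures.
        """
        if not query:
            raise ValueError("query must be nonempty")
        params = {"query": query, "format": "json"}
        if organism:
            params["species"] = organism
        url = f"{self.config.base_url}/findPathwaysByText?" + urllib.parse.urlencode(params)
        body = self._fetch(url, token)
        try:
            payload = json.loads(body.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as e:
            raise ServiceError(200, f"unparseable search response: {e}")
        hits = payload.get("result", []) if isinstance(payload, dict) else []
        refs = []
        for hit in hits:
            wpid = hit.get("id") or hit.get("wpid") or ""
            try:
                refs.append(
                    PathwayRef(
                        wpid=wpid,
                        name=hit.get("name", ""),
                        organism=hit.get("species", hit.get("organism", "")),
                        revision=str(hit.get("revision", "")),
                    )
                )
            except ValueError:
                logger.warning("search hit with malformed id %r skipped", wpid)
        return refs

    def get_pathway_gpml(
        self,
        wpid: str,
        revision: Optional[str] = None,
        token: Optional[CancellationToken] = None,
        bypass_cache: bool = False,
    ) -> str:
        """Download one pathway's GPML text, caching by (wpid, revision).

        The cache file appears only after a complete transfer (written
        to a temp name, then atomically renamed), so cancellation never
        leaves partial documents behind.
        """
        if not WPID_PATTERN.match(wpid):
            raise ValueError(f"invalid WikiPathways id {wpid!r} (expected WP<digits>)")
        cache_file = None
        if self.config.cache_dir is not None:
            cache_file = Path(self.config.cache_dir) / f"{wpid}_{revision or 'latest'}.gpml"
            if cache_file.exists() and not bypass_cache:
                return cache_file.read_text(encoding="utf-8")
        params = {"fileType": "gpml"}
        if revision:
            params["revision"] = revision
        url = f"{self.config.base_url}/getPathway/{wpid}?" + urllib.parse.urlencode(params)
        body = self._fetch(url, token)
        text = body.decode("utf-8")
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            tmp = cache_file.with_suffix(".tmp")
            tmp.write_text(text, encoding="utf-8")
            tmp.replace(cache_file)
        return text
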