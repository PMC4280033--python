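"""Per-user, token-authorized RSS feeds of torrents (broadcatching).

A feed document is ordinary RSS 2.0 with one item per published
torrent, newest first.  Each item's enclosure points at the portal's
.torrent download endpoint *for the requesting user*: both the channel
link and every enclosure URL embed that user's token, so the document a
client polls is personal and the torrents it auto-downloads announce
with the right credentials.  Two users fetching the same feed get
documents identical except for the embedded tokens.

Publishing runs the portal's enforcement path: the uploaded metainfo is
parsed, the BEP-0027 private flag is forced on, the canonical
(post-privatization) bytes are stored, and that info-hash — shared by
every subscriber — becomes announceable on the tracker.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from email.utils import formatdate
from typing import Optional

from . import metainfo as mi
from .authz import Action, ConflictError, PortalStore, TorrentRecord

__all__ = [
    "MEDIA_TYPE",
    "FeedAccessError",
    "NotFoundError",
    "feed_url",
    "torrent_url",
    "generate_feed",
    "download_torrent",
    "publish_torrent",
]

MEDIA_TYPE = "application/x-bittorrent"


class FeedAccessError(PermissionError):
    """The token is not authorized for the requested feed operation."""


class NotFoundError(LookupError):
    """Unknown feed or info-hash."""


def feed_url(base: str, token: str, feed_id: int) -> str:
    return f"{base.rstrip('/')}/{token}/feeds/{feed_id}.rss"


def torrent_url(base: str, token: str, info_hash_hex: str) -> str:
    return f"{base.rstrip('/')}/{token}/torrents/{info_hash_hex}.torrent"


def generate_feed(store: PortalStore, feed_id: int, token: str,
                  portal_base: str, *, secure_channel: bool = True) -> bytes:
    """Render the RSS 2.0 document for one feed and one user.

    Refuses (no partial document) unless the token holds ``fetch_rss``
    on the feed.  Items are sorted newest-first; the guid is the torrent
    info-hash in hex, the pubDate is RFC-822, and the enclosure length
    is the size of the .torrent file itself (the payload travels over
    the swarm, not over HTTP).
    """
    decision = store.authorize(token, feed_id, Action.FETCH_RSS,
                               secure_channel=secure_channel)
    if not decision:
        raise FeedAccessError(decision.reason)
    feed = store.get_feed(feed_id)

    rss = ET.Element("rss", version="2.0")
    channel = ET.SubElement(rss, "channel")
    ET.SubElement(channel, "title").text = feed.name
    ET.SubElement(channel, "description").text = feed.description
    ET.SubElement(channel, "link").text = feed_url(portal_base, token, feed_id)

    for record in store.list_torrents(feed_id):
        ih_hex = record.info_hash.hex()
        item = ET.SubElement(channel, "item")
        ET.SubElement(item, "title").text = record.name
        guid = ET.SubElement(item, "guid", isPermaLink="false")
        guid.text = ih_hex
        ET.SubElement(item, "pubDate").text = formatdate(record.published_at)
        ET.SubElement(item, "enclosure",
                      url=torrent_url(portal_base, token, ih_hex),
                      length=str(len(record.torrent_bytes)),
                      type=MEDIA_TYPE)

    return ET.tostring(rss, encoding="utf-8", xml_declaration=True)


def download_torrent(store: PortalStore, feed_id: int, info_hash: bytes,
                     token: str, tracker_base: str,
                     *, secure_channel: bool = True) -> bytes:
    """The stored privatized metainfo, announce-tokenized for this user.

    Every user's download carries their own announce URL but the same
    info dictionary, so all of them join one swarm.
    """
    decision = store.authorize(token, feed_id, Action.DOWNLOAD_TORRENT,
                               secure_channel=secure_channel)
    if not decision:
        raise FeedAccessError(decision.reason)
    record = store.find_torrent(info_hash)
    if record is None or record.feed_id != feed_id:
        raise NotFoundError(f"no torrent {info_hash.hex()} in feed {feed_id}")
    torrent = mi.Metainfo.from_bytes(record.torrent_bytes)
    return mi.tokenize_announce(torrent, tracker_base, token).to_bytes()


def publish_torrent(store: PortalStore, feed_id: int, torrent_bytes: bytes,
                    token: str, *, published_at: Optional[float] = None,
                    secure_channel: bool = True) -> TorrentRecord:
    """Register an uploaded .torrent with a feed.

    The stored record holds the privatized canonical metainfo; its
    info-hash is the swarm identity all subscribers share.  Duplicate
    info-hashes within a feed are a conflict.
    """
    decision = store.authorize(token, feed_id, Action.PUBLISH_TORRENT,
                               secure_channel=secure_channel)
    if not decision:
        raise FeedAccessError(decision.reason)
    torrent = mi.Metainfo.from_bytes(torrent_bytes)  # raises MetainfoError
    private = mi.privatize(torrent)
    canonical = private.to_bytes()
    info_hash = private.info_hash()
    try:
        return store.add_torrent_record(
            feed_id, info_hash.digest, private.name, canonical,
            private.total_length, published_at,
        )
    except ConflictError:
        raise
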