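# Methods

This note records the model behind `seedportal`, the defaults that
matter, the design choices made where the design was genuinely open, and
what the simulator does and does not show about real deployments.

## The access model

One portal instance controls one network: a single namespace of users,
feeds, torrents and swarms backed by an embedded SQLite database.
Authentication and authorization happen at three points — portal
login/admin calls, RSS feed requests, and tracker announces — and every
decision is logged as a JSON line tagged with its stage.

Roles are assigned per user per feed. The decision matrix is
deny-by-default and exactly:

| action            | none | subscriber | publisher | admin bit |
|-------------------|------|------------|-----------|-----------|
| view_feed         |  –   |     ✓      |     ✓     |     ✓     |
| download_torrent  |  –   |     ✓      |     ✓     |     ✓     |
| announce          |  –   |     ✓      |     ✓     |     ✓     |
| fetch_rss         |  –   |     ✓      |     ✓     |     ✓     |
| publish_torrent   |  –   |     –      |     ✓     |     ✓     |
| manage_feed       |  –   |     –      |     ✓     |     ✓     |
| manage_users      |  –   |     –      |     –     |     ✓     |

An unapproved account, an unknown token, or a rotated token denies
everything regardless of role. The admin bit is "publisher on every
feed" plus user management. *Subscriber* is the default granted role;
the absence of any grant is role *none*.

Open points resolved as package choices: only administrators may demote
a publisher (publishers can grant up to publisher but not revoke a
peer); announcing on a feed where the token holds no role is refused
("forbidden"); feed creation — publisher rights are per-feed, so a first
feed cannot require them — is allowed to administrators and to users
already holding publisher somewhere, and the creator becomes the new
feed's publisher; only the privatized form of an uploaded torrent is
ever served.

Tokens are 32 bytes from the OS CSPRNG, URL-safe, bound to one user and
stored as SHA-256 digests; passwords are salted PBKDF2-HMAC-SHA256
(60,000 iterations). Token transport security is the deployer's duty
(TLS termination in front of the WSGI app); with `require_https: true`
the service refuses any tokened request arriving over plain HTTP.

## Torrent handling

BitTorrent v1 only (20-byte SHA-1 piece digests); the private-flag
mechanism this portal depends on predates v2/hybrid torrents. Bencoding
is strict by default — unsorted or duplicate dictionary keys, leading
zeros and trailing bytes are rejected with a byte offset — because the
info-hash is only stable if the encoded bytes are canonical. A lenient
decode switch accepts real-world sloppiness (re-encoding is always
canonical), and the info-hash of a third-party torrent is computed over
the *verbatim* byte span of its `info` entry, never a re-encoding.

Defaults and conventions: piece length 4 MiB (configurable; floor
16 KiB, the protocol block size); 0-based piece indexing; multi-file
payloads ordered lexicographically by UTF-8 path-component bytes so
directory torrents hash reproducibly on any platform; the user token is
a path segment (`<base>/<token>/announce`) rather than a query
parameter, because deployed clients are known to rewrite query strings;
privatization happens at publication, so the canonical announceable
identity is the post-privatization hash and all subscribers share one
swarm. During payload verification a missing or short file is read as
zero bytes of its declared length: the pieces covering it fail without
shifting the piece framing of everything after it.

## Tracker

The announce pipeline validates parameters, resolves the token,
requires the info-hash to be registered in some feed (a foreign hash is
"unregistered torrent" — the logical partitioning of the private
network), and checks the role matrix, in that order. Failures are
bencoded `failure reason` dictionaries served with HTTP 200 per tracker
convention, except token failures, which also carry 401.

Defaults chosen where the protocol is silent: announce interval 1800 s;
peer timeout 2.5 × interval (one missed keep-alive plus slack) — a
pruned peer is simply re-added by its next announce; at most 50 peers
per response; compact (BEP-0023) responses by default, IPv4 only in
compact form with IPv6 peers falling back to dictionary entries. The
peer registry is in-memory: a tracker restart loses only liveness
state, which the next announce cycle rebuilds. Geolocation for the
dashboard is a pluggable resolver defaulting to a stub that returns
"unknown".

## RSS feeds

RSS 2.0, one item per torrent, newest first. The guid is the info-hash
hex (`isPermaLink="false"`), pubDate is RFC-822, the enclosure media
type is `application/x-bittorrent` and its length is the .torrent file
size. Feed URLs follow `/<token>/feeds/<id>.rss`, mirroring the
announce convention. No pagination: feeds are expected to hold tens of
torrents, not thousands.

## Swarm simulator

The simulator models piece ownership, not bytes or bandwidth: time is
discrete ticks, each node holds a bitfield, and capacities are pieces
per tick (download and upload separately). Per tick: churn events fire;
then each online incomplete node, in node-id order, requests up to its
download capacity of pieces. A request selects the *rarest* missing
piece among those some online peer held at the start of the tick and
can still serve this tick, breaking ties by lowest piece index, then
lowest provider id; the provider's upload capacity is debited. Pieces
gained during a tick become servable at the next tick. The run ends at
the tick limit or when every non-publisher node is complete;
non-convergence is reported in the trace, never raised.

This determinism is the point: the same configuration (including seed)
replays to a byte-identical trace, which makes churn experiments exact
regression tests. A configuration whose initially-online nodes do not
jointly cover all pieces is flagged unrecoverable up front.

What the model emulates: aggregate availability under churn, the
publisher-departure scenario (once a dedicated replica exists, the
origin can leave permanently), recovery of intermittently connected
nodes, and completion ordering. What it deliberately omits: transfer
latency and variable bandwidth, tit-for-tat/choking incentives, piece
subdivision into blocks, endgame mode, and geographic placement.
Passing simulator tests therefore demonstrates the availability logic
and the portal/tracker integration, not wire-level client behaviour —
real-client interop rests on emitting standard metainfo, announce
responses and RSS that stock clients consume.

The storage calculator is `total / (devices × participation)`. Unit
convention: decimal petabytes (10^15 bytes) in, binary gibibytes (2^30
bytes) out by default — the convention mixes a vendor-quoted archive
size with an OS-reported per-device quota, which is how such figures
are usually quoted; an all-binary variant is a one-constant change
(`PIB`). Under either reading the worked 40 PB / 2,883,000-device / 50%
example lands at 25.8–29.1 GiB per device, i.e. within a quarter of the
commonly quoted ~32 GiB round figure.

## Fixtures and problem sizes

All test data is generated at run time: payloads are seeded
`random.Random().randbytes` streams (reproducible cross-platform), so
the repository ships no binary fixtures. Unit tests use 16 KiB pieces
over payloads of tens of KiB to keep hashing trivial; the desk-scale
replication experiment uses a 64 MiB payload at the default 4 MiB piece
size (16 pieces) with 1 publisher and 7 subscribers under scheduled
single-node interruptions — large enough to exercise real piece
arithmetic and churn, small enough that the whole suite runs in
seconds. The service is exercised both by driving the WSGI callable
directly and through a live `wsgiref` socket server.

## Known limitations

- No UDP tracker protocol, DHT, PEX or magnet links (the latter two are
  intentionally incompatible with the private-flag model).
- No `announce-list` multi-tracker extension; one portal is one network.
- The tracker trusts the announce's reported `left` counter, as all
  trackers must; the dashboard is a client self-report.
- SQLite serializes writers; a portal serving thousands of concurrent
  announces would want the store behind a server-grade RDBMS, which the
  `PortalStore` interface permits without API change.
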