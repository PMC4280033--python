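# seedportal

Private, authorization-extended BitTorrent publication for large
scientific datasets.

Moving multi-hundred-GiB genomics payloads between collaborating sites
strains every centralized transfer channel: a single origin server is a
bandwidth bottleneck and a single point of failure, yet most 'omics data
is under controlled-access agreements and cannot go near public
BitTorrent infrastructure. `seedportal` implements the middle path: a
standard BitTorrent swarm — so aggregate download bandwidth grows with
the number of peers, and the original publisher can go offline once one
full replica exists elsewhere — wrapped in a portal that authenticates
and authorizes every request, so only approved collaborators can ever
join a swarm.

The package provides, as a library, a service and a CLI:

- **bencoding** (`seedportal.bencode`) — strict canonical
  encoder/decoder for .torrent files and tracker responses, with exact
  raw-byte slicing of the `info` entry so third-party torrents keep
  their identity.
- **metainfo** (`seedportal.metainfo`) — create, parse, verify and
  transform .torrent files: per-piece SHA-1 checksums (default piece
  size 4 MiB), forced BEP-0027 `private` flag, and per-user announce
  URLs of the form `<tracker>/<token>/announce` that leave the info
  dictionary — and hence the swarm identity — untouched.
- **access control** (`seedportal.authz`) — email/password accounts
  requiring administrator approval; per-user-per-feed roles *none* /
  *subscriber* / *publisher*; a global administrator bit; 256-bit
  URL-safe tokens, stored hashed, rotated atomically.
- **tracker** (`seedportal.tracker`) — an HTTP announce/scrape tracker
  that refuses unknown tokens, unauthorized roles and any info-hash not
  registered in a portal feed; compact (BEP-0023) peer lists; per-node
  completion percentages for the operator dashboard.
- **RSS broadcatching** (`seedportal.feedgen`) — BEP-0036-style feeds:
  one RSS 2.0 document per (feed, user), every enclosure URL carrying
  that user's token, so a stock BitTorrent client subscribed to the feed
  URL auto-downloads everything published to it.
- **swarm simulator** (`seedportal.swarmsim`) — a deterministic
  piece-level model of swarm replication under churn (rarest-first
  piece selection, per-tick capacities, scheduled outages), plus the
  volunteer-storage calculator.

## The core mechanics

A torrent's identity is its **info-hash**, the SHA-1 over the
canonically bencoded `info` dictionary. The portal forces `private = 1`
inside `info` at upload time, so the canonical, distributed info-hash is
the post-privatization one and clients honouring the flag use only the
embedded tracker (no DHT/PEX). Tokenization rewrites only the announce
URL, never `info`: every collaborator's personalized .torrent joins the
same swarm.

Per-node progress is tracked from announces as

    completion % = 100 x (1 - left / total_bytes),  clamped to [0, 100]

and the recoverability of a payload across a churning swarm is governed
by aggregate availability: with per-node piece bitfields b_i and online
set O, the data remains fully downloadable iff

    OR_{i in O} b_i = 1  (all pieces covered)

The simulator exercises exactly this invariant: as long as the union
stays complete at every tick, every subscriber reaches 100%, including
after the publisher permanently departs.

The volunteer-storage calculator estimates the per-device burden of
archiving a dataset across a participating fraction of a device network:
`total_bytes / (devices x participation)`.

## Worked example

```console
$ seedportal create-torrent genome.bin -o genome.torrent
{"output": "genome.torrent", "info_hash": "9f3e3fa90f4a2149bd8c7edfbcf2489269bdb465",
 "piece_length": 4194304, "piece_count": 3, "total_length": 9437184}

$ seedportal verify genome.torrent genome.bin
{"completion_percent": 100.0, "missing_pieces": []}
```

A 9 MiB payload at the default 4 MiB piece size yields ceil(9/4) = 3
pieces; `verify` recomputes every piece digest and reports 100%
completion with no missing pieces.

A churn scenario (1 publisher, 3 subscribers, one subscriber
interrupted at tick 4 and recovering at tick 8):

```console
$ seedportal simulate scenario.yaml
{"availability_always_complete": true,
 "completion_tick": {"pub": 0, "sub1": 16, "sub2": 20, "sub3": 16},
 "converged": true, "initially_recoverable": true,
 "seed": 1, "ticks_run": 20, "transfers": 48}
```

All subscribers complete; the interrupted node finishes 4 ticks later
than its peers — the length of its outage — and the trace is
byte-identical on every rerun of the same scenario.

The storage calculator, for a 40 PB archive over 50% of a
2,883,000-device volunteer network:

```pycon
>>> from seedportal.swarmsim import storage_per_device, PB, GIB
>>> storage_per_device(40 * PB, 2_883_000, 0.5) / GIB
25.84...
```

about 26 GiB of donated storage per participating device (29 GiB if the
archive size is read in binary pebibytes).

Running a portal:

```console
$ seedportal admin --db portal.db bootstrap ops@example.org <password>
$ seedportal serve --config portal.yaml
```

then `POST /register`, approve and grant with `seedportal admin` (or the
`/token/admin/*` endpoints), publish with
`POST /<token>/feeds/<id>/torrents`, and point clients at
`/<token>/feeds/<id>.rss`.

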