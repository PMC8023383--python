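from datetime import datetime, timezone

import pytest

from vaxsent.corpus import PostRecord


def make_post(id="p1", platform="twitter", ts="2020-05-04T12:00:00Z",
              country="GB", region=None, text="covid vaccine news"):
    return PostRecord(
        id=id, platform=platform,
        timestamp=datetime.fromisoformat(ts.replace("Z", "+00:00")),
        country=country, region=region, text=text,
    )


@pytest.fixture
def small_corpus():
    """Four hand-built posts spanning platforms and countries."""
    return [
        make_post("a", "twitter", "2020-05-04T10:00:00Z", "GB", "Kent",
                  "covid vaccine hope great"),
        make_post("b", "facebook", "2020-05-05T10:00:00Z", "GB", "Kent",
                  "coronavirus vaccination fear hoax"),
        make_post("c", "twitter", "2020-05-06T10:00:00Z", "US", "Ohio",
                  "pandemic immunization update report"),
        make_post("d", "facebook", "2020-05-07T10:00:00Z", "FR", None,
                  "covid vaccine great"),
    ]
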