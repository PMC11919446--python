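<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{{ model.title }}</title>
<link rel="stylesheet" href="style.css">
</head>
<body>
<nav id="topnav">
  <span class="brand">{{ model.title }}</span>
  <div class="dropdown">
    <button type="button">Communities overview</button>
    <div class="dropdown-content">
      <a href="#overview">Overview</a>
    </div>
  </div>
  <div class="dropdown">
    <button type="button">Full report</button>
    <div class="dropdown-content">
      {% for anchor, text in model.nav %}
      <a href="#{{ anchor }}">{{ text }}</a>
      {% endfor %}
    </div>
  </div>
  {% if model.home_href %}<a class="home" href="{{ model.home_href }}">All reports</a>{% endif %}
</nav>
<main>
<section id="overview" class="frame overview">
  <h1>Communities overview</h1>
  <ul class="tree">
    {% for m in model.overview.metas %}
    <li><a href="#{{ m.anchor }}">{{ m.title }}</a>
      <ul>
        {% for c in m.communities %}
        <li><a href="#{{ c.anchor }}">{{ c.title }}</a>
          <span class="terms">{{ c.terms|join(', ') }}</span></li>
        {% endfor %}
      </ul>
    </li>
    {% endfor %}
    {% for c in model.overview.lone_communities %}
    <li><a href="#{{ c.anchor }}">{{ c.title }}</a>
      <span class="terms">{{ c.terms|join(', ') }}</span></li>
    {% endfor %}
    {% for t in model.overview.unclustered %}
    <li class="unclustered"><a href="#{{ t.anchor }}">{{ t.title }}</a></li>
    {% endfor %}
  </ul>
  {% for label, rel in model.overview.assets %}
  <div class="toggle-block">
    <button type="button" class="toggle" data-target="overview-asset-{{ loop.index }}">{{ label }}</button>
    <div class="content" id="overview-asset-{{ loop.index }}">
      <img src="{{ rel }}" alt="{{ label }}">
    </div>
  </div>
  {% endfor %}
</section>
{% for frame in model.frames %}
<section id="{{ frame.frame_id }}" class="frame {{ frame.kind }}">
  <h2>{{ frame.title }}</h2>
  {% if frame.description %}<p class="desc">{{ frame.description }}</p>{% endif %}
  {% if frame.links.get('parent') %}
  <p class="links">Meta-community:
    {% for href, text in frame.links['parent'] %}<a href="{{ href }}">{{ text }}</a>{% endfor %}
  </p>
  {% endif %}
  {% if frame.links.get('siblings') %}
  <p class="links">Sibling communities:
    {% for href, text in frame.links['siblings'] %}<a href="{{ href }}">{{ text }}</a>{% if not loop.last %}, {% endif %}{% endfor %}
  </p>
  {% endif %}
  {% if frame.links.get('members') %}
  <p class="links">Member communities:
    {% for href, text in frame.links['members'] %}<a href="{{ href }}">{{ text }}</a>{% if not loop.last %}, {% endif %}{% endfor %}
  </p>
  {% endif %}
  {% if frame.term_table %}
  <table class="terms">
    <thead><tr><th>Database</th><th>Term</th><th>Description</th><th>adj. p</th><th>GoI</th></tr></thead>
    <tbody>
      {% for row in frame.term_table %}
      <tr><td>{{ row.database }}</td><td>{{ row.term_id }}</td>
          <td>{{ row.description }}</td><td>{{ row.padj }}</td><td>{{ row.n_genes }}</td></tr>
      {% endfor %}
    </tbody>
  </table>
  {% endif %}
  {% for label, rel in frame.assets %}
  <div class="toggle-block">
    <button type="button" class="toggle" data-target="{{ frame.frame_id }}-asset-{{ loop.index }}">{{ label }}</button>
    <div class="content" id="{{ frame.frame_id }}-asset-{{ loop.index }}">
      <img src="{{ rel }}" alt="{{ label }}">
    </div>
  </div>
  {% endfor %}
  {% for label, rel in frame.images %}
  <div class="toggle-block">
    <button type="button" class="toggle" data-target="{{ frame.frame_id }}-image-{{ loop.index }}">{{ label }}</button>
    <div class="content" id="{{ frame.frame_id }}-image-{{ loop.index }}">
      <img src="{{ rel }}" alt="{{ label }}">
    </div>
  </div>
  {% endfor %}
  {% if frame.links.get('weak') %}
  <div class="weak-links">
    <h3>Weak gene-set overlap</h3>
    <p>{% for href, text in frame.links['weak'] %}<a href="{{ href }}">{{ text }}</a>{% if not loop.last %}, {% endif %}{% endfor %}</p>
  </div>
  {% endif %}
  {% if frame.gene_links %}
  <div class="toggle-block">
    <button type="button" class="toggle" data-target="{{ frame.frame_id }}-genes">Genes of interest ({{ frame.gene_links|length }})</button>
    <div class="content" id="{{ frame.frame_id }}-genes">
      <ul class="genes">
        {% for g in frame.gene_links %}
        <li>{{ g.gene }}
          <a href="{{ g.gene_url }}" rel="external">NCBI Gene</a>
          <a href="{{ g.pubmed_url }}" rel="external">PubMed</a></li>
        {% endfor %}
      </ul>
    </div>
  </div>
  {% endif %}
</section>
{% endfor %}
</main>
<script src="report.js"></script>
</body>
</html>
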