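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
    <button type="button">Reports</button>
    <div class="dropdown-content">
      {% for r in model.reports %}
      <a href="{{ r.href }}">{{ r.title }}</a>
      {% endfor %}
    </div>
  </div>
</nav>
<main>
<section class="frame overview" id="overview">
  <h1>{{ model.title }}</h1>
  <p>Terms identified as enriched per input FEA:</p>
  <table class="terms">
    <thead><tr><th>FEA</th><th>Enriched terms</th></tr></thead>
    <tbody>
      {% for f in model.fea_summary %}
      <tr><td>{{ f.fea_id }}</td><td>{{ f.n_terms }}</td></tr>
      {% endfor %}
    </tbody>
  </table>
  {% if model.upset_asset %}
  <div class="toggle-block">
    <button type="button" class="toggle" data-target="front-upset">FEA term-set upset plot</button>
    <div class="content" id="front-upset">
      <img src="{{ model.upset_asset }}" alt="FEA term-set upset plot">
    </div>
  </div>
  {% endif %}
  <h2>FEA term-set intersections</h2>
  <ul class="tree">
    {% for r in model.reports %}
    <li><a href="{{ r.href }}">{{ r.title }}</a> — {{ r.n_terms }} shared terms</li>
    {% endfor %}
  </ul>
</section>
</main>
<script src="report.js"></script>
</body>
</html>
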