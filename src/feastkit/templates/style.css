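body {
  font-family: "Helvetica Neue", Arial, sans-serif;
  margin: 0;
  background: #fafafa;
  color: #222;
}
#topnav {
  position: fixed;
  top: 0;
  left: 0;
  right: 0;
  background: #2b3a55;
  color: #fff;
  padding: 0.4em 1em;
  display: flex;
  align-items: center;
  gap: 1em;
  z-index: 10;
}
#topnav .brand { font-weight: bold; margin-right: 1em; }
#topnav a.home { color: #ffd700; text-decoration: none; }
.dropdown { position: relative; display: inline-block; }
.dropdown > button {
  background: none;
  border: 1px solid #ffffff66;
  color: #fff;
  padding: 0.3em 0.8em;
  cursor: pointer;
  border-radius: 4px;
}
.dropdown-content {
  display: none;
  position: absolute;
  background: #fff;
  color: #222;
  min-width: 220px;
  max-height: 70vh;
  overflow-y: auto;
  box-shadow: 0 4px 10px rgba(0,0,0,0.25);
  border-radius: 4px;
}
.dropdown:hover .dropdown-content, .dropdown.open .dropdown-content { display: block; }
.dropdown-content a {
  display: block;
  padding: 0.35em 0.8em;
  color: #2b3a55;
  text-decoration: none;
}
.dropdown-content a:hover { background: #eef2f8; }
main { padding: 4.5em 2em 2em; max-width: 1100px; margin: 0 auto; }
.frame {
  background: #fff;
  border: 1px solid #ddd;
  border-radius: 6px;
  padding: 1em 1.5em;
  margin-bottom: 1.5em;
}
.frame.meta { border-left: 5px solid #c0392b; }
.frame.community { border-left: 5px solid #2980b9; }
.frame.term { border-left: 5px solid #d4ac0d; }
.frame.overview { border-left: 5px solid #7f8c8d; }
.tree { list-style: none; padding-left: 0.5em; }
.tree ul { list-style: none; }
.tree .terms { color: #777; font-size: 0.85em; margin-left: 0.5em; }
table.terms { border-collapse: collapse; margin: 0.8em 0; font-size: 0.9em; }
table.terms th, table.terms td { border: 1px solid #ccc; padding: 0.25em 0.6em; }
table.terms th { background: #eef2f8; }
.toggle-block { margin: 0.6em 0; }
button.toggle {
  background: #eef2f8;
  border: 1px solid #bcd;
  border-radius: 4px;
  padding: 0.3em 0.8em;
  cursor: pointer;
}
.toggle-block .content { display: none; padding: 0.6em 0; }
.toggle-block .content.shown { display: block; }
.toggle-block img { max-width: 100%; height: auto; }
ul.genes { columns: 3; list-style: none; padding-left: 0; font-size: 0.85em; }
ul.genes a { margin-left: 0.4em; font-size: 0.85em; }
.weak-links h3 { margin-bottom: 0.2em; }
.links a { margin-right: 0.3em; }
.desc { color: #555; }
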